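"""Per-branch classifier ensemble over the label hierarchy.

One multi-class network is trained per branch (internal node with >= 2
children).  A branch's training set contains every sample whose truth path
passes *through* the branch parent and extends at least one level below it;
the target is the index of the child whose subtree contains the truth label.
Samples whose truth label IS the branch parent carry no child information and
are excluded from that branch (they still train ancestor branches).

Branch output vectors are softmax probabilities, so each branch's child
scores sum to 1; hierarchy-consistent per-node scores are then obtained by
:mod:`oncotoc.propagation`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .features import EncoderModel, FeatureVector
from .hierarchy import BranchSpec, LabelHierarchy
from .nn import DenseClassifier

log = logging.getLogger(__name__)

DEFAULT_CALL_THRESHOLD = 0.55


@dataclass
class TrainingConfig:
    """Hyperparameters shared by every branch network.

    Defaults mirror the production training recipe: 4 dense layers with a
    256-wide bottleneck, dropout 0.25, learning rate 0.005, cross-entropy
    loss.  Optimizer (Adam), epoch budget, batch size and early stopping are
    this package's choices and are all configurable.
    """

    hidden_dim: int = 256
    n_layers: int = 4
    dropout_rate: float = 0.25
    learning_rate: float = 0.005
    epochs: int = 100
    batch_size: int = 256
    seed: int = 0
    early_stop_patience: int = 10
    val_fraction: float = 0.1
    class_weighting: bool = False

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2")


@dataclass
class BranchNetwork:
    branch: BranchSpec
    net: DenseClassifier

    def branch_scores(self, x: FeatureVector | np.ndarray) -> dict[str, float]:
        """Child-code -> probability for one sample; scores sum to 1."""
        vec = x.values if isinstance(x, FeatureVector) else np.asarray(x, float)
        probs = self.net.predict_proba(vec.reshape(1, -1))[0]
        return dict(zip(self.branch.child_codes, probs.tolist()))


def assign_branch_training_set(
    branch: BranchSpec,
    samples: list[tuple[FeatureVector, str]],
    h: LabelHierarchy,
) -> list[tuple[FeatureVector, int]]:
    """Route (feature vector, truth code) pairs to a branch's training set.

    Returns pairs (vector, child index).  Included iff the truth label lies
    strictly below the branch parent; the label is the index of the child
    whose subtree contains it.
    """
    subtrees = [h.subtree(c) for c in branch.child_codes]
    out: list[tuple[FeatureVector, int]] = []
    for vec, truth in samples:
        h.node(truth)  # raises UnknownCodeError for bad truth codes
        if truth == branch.parent_code:
            continue
        for j, sub in enumerate(subtrees):
            if truth in sub:
                out.append((vec, j))
                break
    return out


def train_branch(
    branch: BranchSpec,
    data: list[tuple[FeatureVector, int]],
    cfg: TrainingConfig,
    seed: int | None = None,
) -> BranchNetwork:
    """Train one branch network on its routed training set.

    Raises ``ValueError`` on empty data or when only one child label is
    represented (a branch that cannot be learned must be treated as
    uniform-score / pass-through by the caller).
    """
    if not data:
        raise ValueError(f"branch {branch.parent_code!r}: empty training set")
    X = np.stack([fv.values for fv, _ in data])
    y = np.array([lab for _, lab in data], int)
    if len(np.unique(y)) < 2:
        raise ValueError(
            f"branch {branch.parent_code!r}: only one child label present; "
            "treat as pass-through/uniform instead of training"
        )
    net = DenseClassifier(
        in_dim=X.shape[1],
        n_classes=len(branch.child_codes),
        hidden_dim=cfg.hidden_dim,
        n_layers=cfg.n_layers,
        dropout_rate=cfg.dropout_rate,
        seed=cfg.seed if seed is None else seed,
    )
    class_weight = None
    if cfg.class_weighting:
        counts = np.bincount(y, minlength=len(branch.child_codes)).astype(float)
        class_weight = np.where(counts > 0, len(y) / np.maximum(counts, 1), 0.0)
        class_weight /= class_weight[counts > 0].mean()
    net.fit(
        X,
        y,
        learning_rate=cfg.learning_rate,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        val_fraction=cfg.val_fraction,
        early_stop_patience=cfg.early_stop_patience,
        class_weight=class_weight,
    )
    return BranchNetwork(branch, net)


class EnsembleModel:
    """Hierarchy + encoder + one trained network per learnable branch."""

    def __init__(
        self,
        hierarchy: LabelHierarchy,
        encoder: EncoderModel,
        networks: dict[str, BranchNetwork],
        call_threshold: float = DEFAULT_CALL_THRESHOLD,
        config: TrainingConfig | None = None,
        untrained: list[str] | None = None,
    ):
        self.hierarchy = hierarchy
        self.encoder = encoder
        self.networks = networks
        self.call_threshold = call_threshold
        self.config = config or TrainingConfig()
        #: branch parents that could not be trained; scored uniformly.
        self.untrained = list(untrained or [])

    # ---------------------------------------------------------------- train

    @classmethod
    def train(
        cls,
        samples: list[tuple[FeatureVector, str]],
        h: LabelHierarchy,
        encoder: EncoderModel,
        cfg: TrainingConfig | None = None,
        call_threshold: float = DEFAULT_CALL_THRESHOLD,
    ) -> "EnsembleModel":
        """Train every branch on its routed subset.

        Branch seeds are derived deterministically from ``cfg.seed`` and the
        branch's position in the canonical branch order, so the whole
        ensemble is reproducible end to end.  Branches with no data or a
        single represented child are recorded in ``untrained`` and scored
        uniformly at inference, with a warning.
        """
        cfg = cfg or TrainingConfig()
        networks: dict[str, BranchNetwork] = {}
        untrained: list[str] = []
        for k, branch in enumerate(h.branches()):
            routed = assign_branch_training_set(branch, samples, h)
            seed = int(np.random.SeedSequence([cfg.seed, k]).generate_state(1)[0] % (2**31))
            try:
                networks[branch.parent_code] = train_branch(branch, routed, cfg, seed=seed)
            except ValueError as exc:
                log.warning(
                    "branch %r left untrained (%s); uniform scores at inference",
                    branch.parent_code,
                    exc,
                )
                untrained.append(branch.parent_code)
        if not networks:
            raise ValueError("no trainable branches: every branch was degenerate")
        return cls(h, encoder, networks, call_threshold, cfg, untrained)

    # ------------------------------------------------------------- inference

    def branch_outputs(self, x: FeatureVector | np.ndarray) -> dict[str, dict[str, float]]:
        """Per-branch child score maps for one sample (untrained -> uniform)."""
        out: dict[str, dict[str, float]] = {}
        for branch in self.hierarchy.branches():
            net = self.networks.get(branch.parent_code)
            if net is None:
                k = len(branch.child_codes)
                out[branch.parent_code] = {c: 1.0 / k for c in branch.child_codes}
            else:
                out[branch.parent_code] = net.branch_scores(x)
        return out

    # --------------------------------------------------------------- persist

    def save(self, model_dir) -> None:
        d = Path(model_dir)
        d.mkdir(parents=True, exist_ok=True)
        self.hierarchy.save(d / "hierarchy.json")
        self.encoder.save(d / "encoder.json")
        for parent, bn in self.networks.items():
            np.savez(d / f"branch_{parent}.npz", **bn.net.get_params())
        manifest = {
            "call_threshold": self.call_threshold,
            "config": asdict(self.config),
            "untrained": self.untrained,
            "branches": {
                parent: {
                    "child_codes": list(bn.branch.child_codes),
                    "in_dim": bn.net.in_dim,
                }
                for parent, bn in self.networks.items()
            },
        }
        with open(d / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, model_dir) -> "EnsembleModel":
        d = Path(model_dir)
        h = LabelHierarchy.load(d / "hierarchy.json")
        enc = EncoderModel.load(d / "encoder.json")
        with open(d / "manifest.json") as fh:
            manifest = json.load(fh)
        cfg = TrainingConfig(**manifest["config"])
        networks: dict[str, BranchNetwork] = {}
        by_parent = {b.parent_code: b for b in h.branches()}
        for parent, info in manifest["branches"].items():
            branch = by_parent[parent]
            if list(branch.child_codes) != info["child_codes"]:
                raise ValueError(f"model/hierarchy mismatch at branch {parent!r}")
            net = DenseClassifier(
                in_dim=info["in_dim"],
                n_classes=len(branch.child_codes),
                hidden_dim=cfg.hidden_dim,
                n_layers=cfg.n_layers,
                dropout_rate=cfg.dropout_rate,
                seed=cfg.seed,
            )
            with np.load(d / f"branch_{parent}.npz") as z:
                net.set_params({k: z[k] for k in z.files})
            networks[parent] = BranchNetwork(branch, net)
        return cls(h, enc, networks, manifest["call_threshold"], cfg, manifest["untrained"])


# Spec-level alias
train_ensemble = EnsembleModel.train
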