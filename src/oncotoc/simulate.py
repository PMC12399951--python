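"""Synthetic cohort generator with hierarchy-structured signal.

The simulator produces the three cohort tables (expression, variants,
metadata) plus a truth map, with the statistical structure the classifier
assumes:

* **Hierarchical expression signatures.**  Every hierarchy node owns a
  sparse effect vector over genes (drawn once per node from the cohort
  seed).  A sample's log2 expression is a shared baseline plus the summed
  effect vectors along its truth path plus Gaussian noise, so sibling
  subcategories share their ancestors' signal and differ only in their own —
  the nesting the branch networks are built to exploit.
* **Label-specific variant enrichment.**  Each label enriches a few panel
  genes; variants elsewhere occur at a background rate.  VAF and supporting
  reads are drawn so a configurable fraction clears the reportability
  filter (VAF >= 5%, support >= 5).
* **Sex priors** per label (e.g. gynecologic labels ~ all female).
* **Platform batch effects** as per-platform multiplicative TPM factors.
* **Metastatic noise inflation**: metastatic samples get their expression
  noise standard deviation multiplied by a factor >= 1, degrading their
  separability relative to primaries.
* **CUP cases** are ordinary tumors whose submitted label is withheld
  (replaced by the CUP marker); the hidden truth stays in the truth map so
  call behaviour on CUP strata can be evaluated against ground truth.

Everything is drawn from one seed; a fixed config + seed reproduces the
cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import ExpressionProfile, SampleMeta, VariantRecord
from .hierarchy import CUP_MARKER, LabelHierarchy


def _default_panel() -> list[str]:
    return [f"PANEL{i:03d}" for i in range(30)]


@dataclass
class SimulationConfig:
    hierarchy: LabelHierarchy
    n_samples: int = 300
    cup_fraction: float = 0.1
    metastatic_fraction: float = 0.4
    n_genes: int = 200
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    node_effect_size: float = 2.0
    effect_fraction: float = 0.3
    within_class_sd: float = 1.0
    metastatic_noise_inflation: float = 1.5
    platform_factors: dict[str, float] = field(
        default_factory=lambda: {"P1": 1.0, "P2": 2.5}
    )
    variant_panel: list[str] = field(default_factory=_default_panel)
    enriched_genes_per_label: int = 3
    enriched_variant_rate: float = 0.4
    background_variant_rate: float = 0.02
    reportable_fraction: float = 0.9
    sex_prior_per_label: dict[str, float] = field(default_factory=dict)
    default_sex_prior: float = 0.5  # P(male)
    low_tumor_content_fraction: float = 0.05
    label_priors: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        for name in (
            "cup_fraction",
            "metastatic_fraction",
            "effect_fraction",
            "reportable_fraction",
            "background_variant_rate",
            "enriched_variant_rate",
            "default_sex_prior",
            "low_tumor_content_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.metastatic_noise_inflation < 1.0:
            raise ValueError("metastatic_noise_inflation must be >= 1")
        if self.within_class_sd <= 0:
            raise ValueError("within_class_sd must be positive")


@dataclass
class SimulatedCohort:
    profiles: list[ExpressionProfile]
    variants: list[VariantRecord]
    meta: list[SampleMeta]
    truth: dict[str, str]  # includes the hidden truth of CUP samples

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.meta]


def _node_effects(cfg: SimulationConfig, genes: list[str]) -> dict[str, np.ndarray]:
    """Per-node sparse effect vectors, drawn deterministically per node.

    Each node's RNG is seeded from (cohort seed, node index in sorted order)
    so effects do not depend on the per-sample draws.
    """
    effects: dict[str, np.ndarray] = {}
    codes = sorted(c for c in cfg.hierarchy.nodes if c != cfg.hierarchy.root_code)
    n_hit = max(1, int(round(cfg.effect_fraction * len(genes))))
    for k, code in enumerate(codes):
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 1000 + k]).generate_state(1)[0]
        )
        vec = np.zeros(len(genes))
        hit = rng.choice(len(genes), size=n_hit, replace=False)
        vec[hit] = rng.normal(0.0, cfg.node_effect_size, size=n_hit)
        effects[code] = vec
    return effects


def _label_variant_genes(cfg: SimulationConfig) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    codes = sorted(c for c in cfg.hierarchy.nodes if c != cfg.hierarchy.root_code)
    panel = cfg.variant_panel
    k = min(cfg.enriched_genes_per_label, len(panel))
    for j, code in enumerate(codes):
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 2000 + j]).generate_state(1)[0]
        )
        out[code] = list(rng.choice(panel, size=k, replace=False))
    return out


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Draw a full cohort; see the module docstring for the generative model."""
    h = cfg.hierarchy
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    effects = _node_effects(cfg, genes)
    var_genes = _label_variant_genes(cfg)

    labels = list(h.reportable_codes)
    if not labels:
        raise ValueError("hierarchy has no reportable labels to draw truths from")
    if cfg.label_priors:
        missing = set(cfg.label_priors) - set(labels)
        if missing:
            raise ValueError(f"label_priors reference unknown labels {sorted(missing)}")
        p = np.array([cfg.label_priors.get(c, 0.0) for c in labels])
        if p.sum() <= 0:
            raise ValueError("label_priors sum to zero")
        p = p / p.sum()
    else:
        p = np.full(len(labels), 1.0 / len(labels))

    baseline = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_genes)
    platforms = sorted(cfg.platform_factors)

    profiles, variants, metas = [], [], []
    truth: dict[str, str] = {}
    for i in range(cfg.n_samples):
        sid = f"S{i:05d}"
        code = labels[rng.choice(len(labels), p=p)]
        truth[sid] = code
        path = h.path_to_root(code)

        is_met = rng.random() < cfg.metastatic_fraction
        is_cup = rng.random() < cfg.cup_fraction
        platform = platforms[rng.integers(len(platforms))]
        sd = cfg.within_class_sd * (cfg.metastatic_noise_inflation if is_met else 1.0)

        logx = baseline.copy()
        for node in path:
            logx += effects[node]
        logx += rng.normal(0.0, sd, size=cfg.n_genes)
        tpm = np.exp2(logx) * cfg.platform_factors[platform]
        profiles.append(
            ExpressionProfile(
                sample_id=sid,
                tpm={g: float(v) for g, v in zip(genes, tpm)},
                platform_id=platform,
            )
        )

        enriched = set(var_genes[code])
        for gene in cfg.variant_panel:
            rate = cfg.enriched_variant_rate if gene in enriched else cfg.background_variant_rate
            if rng.random() >= rate:
                continue
            reportable = rng.random() < cfg.reportable_fraction
            if reportable:
                classification = "pathogenic" if rng.random() < 0.7 else "likely_pathogenic"
                vaf = float(rng.uniform(0.05, 0.6))
                support = int(rng.integers(5, 200))
            else:
                # fails at least one reportability criterion
                mode = rng.integers(3)
                classification = "vus" if mode == 0 else "pathogenic"
                vaf = float(rng.uniform(0.0, 0.049)) if mode == 1 else float(rng.uniform(0.05, 0.6))
                support = int(rng.integers(0, 5)) if mode == 2 else int(rng.integers(5, 200))
            variants.append(VariantRecord(sid, gene, classification, vaf, support))

        p_male = cfg.sex_prior_per_label.get(code, cfg.default_sex_prior)
        sex = "male" if rng.random() < p_male else "female"
        tc = (
            float(rng.uniform(5, 20))
            if rng.random() < cfg.low_tumor_content_fraction
            else float(rng.uniform(20, 100))
        )
        metas.append(
            SampleMeta(
                sample_id=sid,
                sex=sex,
                site_class="metastatic" if is_met else "primary",
                tumor_content=round(tc, 1),
                submitted_label=CUP_MARKER if is_cup else code,
            )
        )

    return SimulatedCohort(profiles, variants, metas, truth)


# ---------------------------------------------------------------------------
# Worked hierarchical-metric examples on a three-level toy hierarchy.


def toy_hierarchy() -> LabelHierarchy:
    """Three-level hierarchy used by the worked metric examples:
    root -> {A, B}; A -> {A1, A2}; A1 -> {A1a, A1b}."""
    recs = [
        {"code": "root", "name": "Tissue", "parent": None, "reportable": False},
        {"code": "A", "name": "Category A", "parent": "root"},
        {"code": "B", "name": "Category B", "parent": "root"},
        {"code": "A1", "name": "Subcategory A1", "parent": "A"},
        {"code": "A2", "name": "Subcategory A2", "parent": "A"},
        {"code": "A1a", "name": "Subtype A1a", "parent": "A1"},
        {"code": "A1b", "name": "Subtype A1b", "parent": "A1"},
    ]
    return LabelHierarchy.from_records(recs)


def worked_example_fixtures() -> tuple[LabelHierarchy, list[tuple[list[str], list[str]]]]:
    """Four (prediction path, truth path) pairs illustrating the per-sample
    hierarchical metrics, with expected (hPPV, hSens) of
    (1, 1), (1, 2/3), (2/3, 2/3), (1, 1):

    a. exact three-level agreement;
    b. prediction stops one level short of a three-level truth;
    c. agreement at two levels, wrong terminal subtype;
    d. prediction one level *deeper* than the truth, inside its subtree
       (a more granular call than the submitted diagnosis).
    """
    h = toy_hierarchy()
    cases = [
        (["A", "A1", "A1a"], ["A", "A1", "A1a"]),  # (a)
        (["A", "A1"], ["A", "A1", "A1a"]),  # (b)
        (["A", "A1", "A1b"], ["A", "A1", "A1a"]),  # (c)
        (["A", "A1", "A1a"], ["A", "A1"]),  # (d)
    ]
    return h, cases
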