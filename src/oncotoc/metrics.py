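"""Hierarchical and flat evaluation metrics.

Per-sample hierarchical metrics compare the *paths* (root excluded) of the
predicted and true labels:

* hSens = |T ∩ P| / |T| — the fraction of true-path nodes the prediction
  recovered;
* hPPV = |P ∩ C(T)| / |P| — the fraction of predicted-path nodes that are
  correct, where the truth closure C(T) adds the descendants of the truth
  terminal to T, so a *more granular* prediction inside the truth subtree is
  fully credited (a common situation when the submitted diagnosis omits the
  subtype).

Both range over [0, 1] and are averaged across called samples only; no-call
samples contribute to the call rate but not to accuracy metrics, matching
how validation metrics are conventionally reported for thresholded
classifiers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import CUP_MARKER, LabelHierarchy, UNMAPPED
from .propagation import CallResult


def truth_closure(truth_path: list[str], h: LabelHierarchy) -> set[str]:
    """Truth-path nodes plus all descendants of the truth terminal node."""
    if not truth_path:
        raise ValueError("empty truth path")
    return set(truth_path) | h.descendants(truth_path[-1])


def sample_hppv(pred_path: list[str], truth_path: list[str], h: LabelHierarchy) -> float:
    """Per-sample hierarchical positive predictive value; see module docs."""
    if not pred_path:
        raise ValueError("hPPV undefined for an empty prediction path (no-call)")
    closure = truth_closure(truth_path, h)
    return sum(1 for c in pred_path if c in closure) / len(pred_path)


def sample_hsens(pred_path: list[str], truth_path: list[str], h: LabelHierarchy) -> float:
    """Per-sample hierarchical sensitivity: |T ∩ P| / |T|."""
    if not truth_path:
        raise ValueError("hSens undefined for an empty truth path")
    pred = set(pred_path)
    return sum(1 for c in truth_path if c in pred) / len(truth_path)


@dataclass
class MetricsReport:
    n_total: int
    n_called: int
    call_rate: float
    hppv_mean: float
    hsens_mean: float
    top1_ppv: float
    top2_ppv: float
    per_major: dict[str, dict[str, float]]
    confusion_major: pd.DataFrame
    call_rate_cup: float | None = None
    call_rate_non_cup: float | None = None

    def to_dict(self) -> dict:
        d = {
            "n_total": self.n_total,
            "n_called": self.n_called,
            "call_rate": self.call_rate,
            "hppv_mean": self.hppv_mean,
            "hsens_mean": self.hsens_mean,
            "top1_ppv": self.top1_ppv,
            "top2_ppv": self.top2_ppv,
            "per_major": self.per_major,
            "confusion_major": {
                "index": list(self.confusion_major.index),
                "columns": list(self.confusion_major.columns),
                "counts": self.confusion_major.values.tolist(),
            },
        }
        if self.call_rate_cup is not None:
            d["call_rate_cup"] = self.call_rate_cup
        if self.call_rate_non_cup is not None:
            d["call_rate_non_cup"] = self.call_rate_non_cup
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def call_rate(calls: list[CallResult]) -> float:
    """Called samples / total samples."""
    if not calls:
        raise ValueError("empty cohort")
    return sum(c.is_call for c in calls) / len(calls)


def evaluate_cohort(
    calls: list[CallResult],
    truths: dict[str, str],
    h: LabelHierarchy,
) -> MetricsReport:
    """Cohort-level metrics over a list of thresholded calls.

    ``truths`` maps sample_id to a hierarchy code; samples whose truth is the
    CUP marker or unmapped contribute to call rates only.  Accuracy metrics
    (hPPV/hSens means, top-1/top-2 PPV, per-major PPV and sensitivity, the
    major-level confusion matrix) are computed over called, truth-mapped
    samples.
    """
    if not calls:
        raise ValueError("empty cohort")
    for sid, code in truths.items():
        if code not in (CUP_MARKER, UNMAPPED):
            h.node(code)  # raises UnknownCodeError

    is_cup = {
        c.sample_id: truths.get(c.sample_id) in (CUP_MARKER, UNMAPPED, None) for c in calls
    }
    cup_calls = [c for c in calls if is_cup[c.sample_id]]
    noncup_calls = [c for c in calls if not is_cup[c.sample_id]]

    hppvs, hsenss, top1_hits, top2_hits = [], [], [], []
    rows = []  # (truth_major, pred_major) over called mapped samples
    for c in noncup_calls:
        if not c.is_call:
            continue
        truth_path = h.path_to_root(truths[c.sample_id])
        hppvs.append(sample_hppv(c.called_path, truth_path, h))
        hsenss.append(sample_hsens(c.called_path, truth_path, h))
        truth_major = truth_path[0]
        top1_hits.append(truth_major == c.top1_major)
        top2_hits.append(truth_major in c.top2_majors)
        rows.append((truth_major, c.called_path[0]))

    majors = list(h.majors)
    conf = pd.DataFrame(0, index=majors, columns=majors, dtype=int)
    for truth_major, pred_major in rows:
        conf.loc[pred_major, truth_major] += 1

    per_major: dict[str, dict[str, float]] = {}
    for m in majors:
        n_pred = int(conf.loc[m].sum())
        n_truth = int(conf[m].sum())
        tp = int(conf.loc[m, m])
        per_major[m] = {
            "ppv": tp / n_pred if n_pred else float("nan"),
            "sensitivity": tp / n_truth if n_truth else float("nan"),
            "n": n_truth,
        }

    def _rate(cs):
        return sum(c.is_call for c in cs) / len(cs) if cs else None

    nan = float("nan")
    return MetricsReport(
        n_total=len(calls),
        n_called=sum(c.is_call for c in calls),
        call_rate=call_rate(calls),
        hppv_mean=float(np.mean(hppvs)) if hppvs else nan,
        hsens_mean=float(np.mean(hsenss)) if hsenss else nan,
        top1_ppv=float(np.mean(top1_hits)) if top1_hits else nan,
        top2_ppv=float(np.mean(top2_hits)) if top2_hits else nan,
        per_major=per_major,
        confusion_major=conf,
        call_rate_cup=_rate(cup_calls),
        call_rate_non_cup=_rate(noncup_calls),
    )
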