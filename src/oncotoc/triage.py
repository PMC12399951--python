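"""Pathology-review triage rules for classifier results.

After scoring, each case is triaged against the submitted diagnosis.  A
*critical value discrepancy* is opened when a high-confidence prediction
(score at or above the discrepancy threshold, default 0.90) either assigns a
label to a CUP case or contradicts the submitted diagnosis of a non-CUP
case.  What happens next depends on orthogonal evidence — imaging, IHC,
hallmark fusions, viral reads, mutational signatures — which is curated
review input, never a model feature.

Rules, applied in order (first match wins for the action):

1. no call                                             -> no_action
2. non-CUP, called major matches the submitted major   -> no_action
3. discrepancy candidate with score >= 0.90            -> discrepancy opened
4. CUP, score >= 0.90, any evidence supports the call  -> diagnosis_change_eligible
5. CUP, score >= 0.90, no supporting evidence          -> discretionary_lineage_change
6. non-CUP discrepancy, submitted label scores 0
   or call score >= 0.90                               -> confirmatory_testing
7. otherwise                                           -> report_only
                                                          (discretionary change offered)

The 0.90 threshold is deterministic here but discretionary in practice
(clinical reviewers may deviate); it is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import pandas as pd

from .hierarchy import CUP_MARKER, LabelHierarchy, UNMAPPED
from .propagation import CallResult, ScoreTree

TRI_STATES = ("supports_call", "contradicts_call", "absent")

ACTIONS = (
    "no_action",
    "report_only",
    "discretionary_lineage_change",
    "diagnosis_change_eligible",
    "confirmatory_testing",
)

DEFAULT_DISCREPANCY_THRESHOLD = 0.90


@dataclass(frozen=True)
class OrthogonalEvidence:
    ihc_support: str = "absent"
    hallmark_fusion: str = "absent"
    viral_reads: str = "absent"
    mutational_signature: str = "absent"
    imaging_or_history: str = "absent"

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v not in TRI_STATES:
                raise ValueError(f"{f.name}={v!r}; expected one of {TRI_STATES}")

    @property
    def any_supports(self) -> bool:
        return any(getattr(self, f.name) == "supports_call" for f in fields(self))


@dataclass
class TriageDecision:
    sample_id: str
    discrepancy_opened: bool
    action: str
    rationale: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.action != "no_action" and not self.rationale:
            raise ValueError("non-trivial action requires at least one fired rule id")


def triage(
    call: CallResult,
    tree: ScoreTree,
    submitted: str,
    h: LabelHierarchy,
    evidence: OrthogonalEvidence | None = None,
    discrepancy_threshold: float = DEFAULT_DISCREPANCY_THRESHOLD,
) -> TriageDecision:
    """Apply the review rules (module docstring) to one scored case.

    ``submitted`` is the mapped submitted diagnosis code or the CUP marker;
    a non-CUP code absent from the hierarchy is an error.  Concordance
    (rule 2) is judged at the major-category level; rule 6 reads the
    propagated score of the exact submitted label from ``tree``.
    """
    if call.sample_id != tree.sample_id:
        raise ValueError("call/tree sample mismatch")
    evidence = evidence or OrthogonalEvidence()
    is_cup = submitted in (CUP_MARKER, UNMAPPED)
    if not is_cup:
        submitted_major = h.path_to_root(submitted)[0]  # raises UnknownCodeError

    # R1: nothing was called — nothing to review.
    if not call.is_call:
        return TriageDecision(call.sample_id, False, "no_action", ["R1"])

    # R2: concordant non-CUP case.
    if not is_cup and submitted_major == call.called_path[0]:
        return TriageDecision(call.sample_id, False, "no_action", ["R2"])

    # From here the case is a discrepancy candidate: a CUP with a call, or a
    # non-CUP whose call contradicts the submitted diagnosis.
    fired: list[str] = []
    high_conf = call.call_score >= discrepancy_threshold
    opened = high_conf  # R3
    if opened:
        fired.append("R3")

    if is_cup:
        if high_conf and evidence.any_supports:
            fired.append("R4")
            return TriageDecision(call.sample_id, opened, "diagnosis_change_eligible", fired)
        if high_conf:
            fired.append("R5")
            return TriageDecision(call.sample_id, opened, "discretionary_lineage_change", fired)
        fired.append("R7")
        return TriageDecision(call.sample_id, opened, "report_only", fired)

    if tree.node_scores.get(submitted, 0.0) == 0.0 or high_conf:
        fired.append("R6")
        return TriageDecision(call.sample_id, opened, "confirmatory_testing", fired)
    fired.append("R7")
    return TriageDecision(call.sample_id, opened, "report_only", fired)


def triage_cohort(
    calls: list[CallResult],
    trees: dict[str, ScoreTree],
    submitted: dict[str, str],
    h: LabelHierarchy,
    evidence: dict[str, OrthogonalEvidence] | None = None,
    discrepancy_threshold: float = DEFAULT_DISCREPANCY_THRESHOLD,
) -> list[TriageDecision]:
    evidence = evidence or {}
    return [
        triage(
            c,
            trees[c.sample_id],
            submitted.get(c.sample_id, CUP_MARKER),
            h,
            evidence.get(c.sample_id),
            discrepancy_threshold,
        )
        for c in calls
    ]


def cohort_triage_summary(
    decisions: list[TriageDecision],
    submitted: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Count decisions per action, stratified CUP vs non-CUP when metadata
    is supplied; includes fractions of the stratum total."""
    if not decisions:
        raise ValueError("empty cohort")
    rows = []
    for d in decisions:
        stratum = "all"
        if submitted is not None:
            stratum = (
                "CUP"
                if submitted.get(d.sample_id, CUP_MARKER) in (CUP_MARKER, UNMAPPED)
                else "non-CUP"
            )
        rows.append(
            {"stratum": stratum, "action": d.action, "discrepancy": d.discrepancy_opened}
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["stratum", "action"])
        .agg(n=("action", "size"), n_discrepancy=("discrepancy", "sum"))
        .reset_index()
    )
    totals = df.groupby("stratum").size().to_dict()
    out["fraction"] = out.apply(lambda r: r["n"] / totals[r["stratum"]], axis=1)
    return out
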