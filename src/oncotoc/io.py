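"""Readers and writers for the tab-separated interchange formats.

Formats (all TSV, ``#``-prefixed provenance header lines are ignored):

* expression: rows = genes, columns = samples, values = TPM;
* platforms:  sample_id, platform_id (companion to expression);
* variants:   sample_id, gene, classification, vaf, support;
* metadata:   sample_id, sex, site_class, tumor_content, submitted_label;
* truth:      sample_id, truth_code;
* evidence:   sample_id + five tri-state orthogonal-evidence columns;
* scores:     sample_id, one column per hierarchy code, plus call columns.

Validation errors carry the offending row/column so malformed inputs are
diagnosable; samples missing from any required table are excluded with a
warning rather than failing the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import ExpressionProfile, SampleMeta, VariantRecord
from .hierarchy import LabelHierarchy
from .propagation import CallResult, NO_CALL, ScoreTree
from .simulate import SimulatedCohort
from .triage import OrthogonalEvidence, TriageDecision

log = logging.getLogger(__name__)


def provenance_header(seed=None, config: dict | None = None) -> str:
    lines = [f"# oncotoc {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        lines.append(f"# config_sha256: {digest}")
    return "\n".join(lines) + "\n"


def _write_tsv(df: pd.DataFrame, path, seed=None, config=None, index=False, index_label=None):
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config))
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: malformed header, missing column(s) {missing}")


# ----------------------------------------------------------------- expression


def read_expression(expression_path, platform_path=None) -> list[ExpressionProfile]:
    df = _read_tsv(expression_path, index_col=0)
    platforms: dict[str, str] = {}
    if platform_path is not None:
        pdf = _read_tsv(platform_path)
        _require_columns(pdf, ["sample_id", "platform_id"], platform_path)
        platforms = dict(zip(pdf["sample_id"].astype(str), pdf["platform_id"].astype(str)))
    mat = df.apply(pd.to_numeric, errors="coerce")
    if mat.isna().any().any():
        col = mat.columns[mat.isna().any()][0]
        gene = mat.index[mat[col].isna()][0]
        raise ValueError(
            f"{expression_path}: non-numeric TPM at gene {gene!r}, sample {col!r}"
        )
    if (mat.values < 0).any():
        i, j = np.argwhere(mat.values < 0)[0]
        raise ValueError(
            f"{expression_path}: negative TPM at gene {mat.index[i]!r}, "
            f"sample {mat.columns[j]!r}"
        )
    return [
        ExpressionProfile(
            sample_id=str(sid),
            tpm={str(g): float(v) for g, v in mat[sid].items()},
            platform_id=platforms.get(str(sid), "default"),
        )
        for sid in mat.columns
    ]


def write_expression(profiles: list[ExpressionProfile], expression_path, platform_path=None, seed=None):
    genes = sorted({g for p in profiles for g in p.tpm})
    df = pd.DataFrame(
        {p.sample_id: [p.tpm.get(g, 0.0) for g in genes] for p in profiles}, index=genes
    )
    _write_tsv(df, expression_path, seed=seed, index=True, index_label="gene")
    if platform_path is not None:
        pdf = pd.DataFrame(
            {"sample_id": [p.sample_id for p in profiles],
             "platform_id": [p.platform_id for p in profiles]}
        )
        _write_tsv(pdf, platform_path, seed=seed)


# ------------------------------------------------------------------- variants


def read_variants(path) -> list[VariantRecord]:
    df = _read_tsv(path, dtype=str)
    _require_columns(df, ["sample_id", "gene", "classification", "vaf", "support"], path)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                VariantRecord(
                    sample_id=str(row["sample_id"]),
                    gene=str(row["gene"]),
                    classification=str(row["classification"]),
                    vaf=float(row["vaf"]),
                    support=int(row["support"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def write_variants(records: list[VariantRecord], path, seed=None):
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "gene": r.gene,
                "classification": r.classification,
                "vaf": r.vaf,
                "support": r.support,
            }
            for r in records
        ],
        columns=["sample_id", "gene", "classification", "vaf", "support"],
    )
    _write_tsv(df, path, seed=seed)


# ------------------------------------------------------------------- metadata


def read_meta(path) -> list[SampleMeta]:
    df = _read_tsv(path, dtype=str)
    _require_columns(
        df, ["sample_id", "sex", "site_class", "tumor_content", "submitted_label"], path
    )
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                SampleMeta(
                    sample_id=str(row["sample_id"]),
                    sex=str(row["sex"]),
                    site_class=str(row["site_class"]),
                    tumor_content=float(row["tumor_content"]),
                    submitted_label=str(row["submitted_label"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def write_meta(metas: list[SampleMeta], path, seed=None):
    df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "sex": m.sex,
                "site_class": m.site_class,
                "tumor_content": m.tumor_content,
                "submitted_label": m.submitted_label,
            }
            for m in metas
        ],
        columns=["sample_id", "sex", "site_class", "tumor_content", "submitted_label"],
    )
    _write_tsv(df, path, seed=seed)


def read_truth(path) -> dict[str, str]:
    df = _read_tsv(path, dtype=str)
    _require_columns(df, ["sample_id", "truth_code"], path)
    return dict(zip(df["sample_id"], df["truth_code"]))


def write_truth(truth: dict[str, str], path, seed=None):
    df = pd.DataFrame(
        {"sample_id": list(truth), "truth_code": [truth[s] for s in truth]}
    )
    _write_tsv(df, path, seed=seed)


# ---------------------------------------------------------------- table set


def read_tables(
    expression_path, platform_path, variants_path, meta_path
) -> tuple[list[ExpressionProfile], list[VariantRecord], list[SampleMeta]]:
    """Read and reconcile the cohort tables.

    Samples must appear in both expression and metadata; those missing from
    either are excluded with a warning (variants are per-sample optional —
    a tumor may genuinely carry no reportable variant).
    """
    profiles = read_expression(expression_path, platform_path)
    variants = read_variants(variants_path) if variants_path else []
    metas = read_meta(meta_path)

    have_expr = {p.sample_id for p in profiles}
    have_meta = {m.sample_id for m in metas}
    common = have_expr & have_meta
    for missing, where in ((have_meta - have_expr, "expression"), (have_expr - have_meta, "metadata")):
        if missing:
            log.warning(
                "%d sample(s) missing from %s table, excluded: %s",
                len(missing),
                where,
                sorted(missing)[:5],
            )
    profiles = [p for p in profiles if p.sample_id in common]
    metas = [m for m in metas if m.sample_id in common]
    variants = [v for v in variants if v.sample_id in common]
    return profiles, variants, metas


def write_cohort(cohort: SimulatedCohort, outdir, seed=None) -> dict[str, Path]:
    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": d / "expression.tsv",
        "platforms": d / "platforms.tsv",
        "variants": d / "variants.tsv",
        "meta": d / "meta.tsv",
        "truth": d / "truth.tsv",
    }
    write_expression(cohort.profiles, paths["expression"], paths["platforms"], seed=seed)
    write_variants(cohort.variants, paths["variants"], seed=seed)
    write_meta(cohort.meta, paths["meta"], seed=seed)
    write_truth(cohort.truth, paths["truth"], seed=seed)
    return paths


# --------------------------------------------------------------------- scores


def write_scores(
    trees: list[ScoreTree], calls: list[CallResult], h: LabelHierarchy, path, seed=None
):
    codes = sorted(h.nodes)
    by_id = {c.sample_id: c for c in calls}
    rows = []
    for t in trees:
        c = by_id[t.sample_id]
        row = {"sample_id": t.sample_id}
        row.update({code: t.node_scores.get(code, 0.0) for code in codes})
        row["called_path"] = "|".join(c.called_path) if c.is_call else NO_CALL
        row["call_score"] = c.call_score
        row["top1_major"] = c.top1_major
        row["top2_majors"] = "|".join(c.top2_majors)
        row["no_call"] = int(not c.is_call)
        row["threshold_used"] = c.threshold_used
        rows.append(row)
    _write_tsv(pd.DataFrame(rows), path, seed=seed)


def read_scores(path, h: LabelHierarchy) -> tuple[list[ScoreTree], list[CallResult]]:
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "called_path", "call_score", "top1_major"], path)
    codes = [c for c in sorted(h.nodes) if c in df.columns]
    trees, calls = [], []
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        trees.append(ScoreTree(sid, {c: float(row[c]) for c in codes}))
        raw_path = str(row["called_path"])
        path_list = [] if raw_path == NO_CALL else raw_path.split("|")
        top2 = tuple(str(row["top2_majors"]).split("|"))
        calls.append(
            CallResult(
                sample_id=sid,
                called_path=path_list,
                call_score=float(row["call_score"]),
                top1_major=str(row["top1_major"]),
                top2_majors=(top2[0], top2[-1]),
                threshold_used=float(row.get("threshold_used", 0.55)),
            )
        )
    return trees, calls


# ------------------------------------------------------------------- evidence


def read_evidence(path) -> dict[str, OrthogonalEvidence]:
    df = _read_tsv(path, dtype=str)
    cols = [f.name for f in dc_fields(OrthogonalEvidence)]
    _require_columns(df, ["sample_id"] + cols, path)
    out = {}
    for i, row in df.iterrows():
        try:
            out[str(row["sample_id"])] = OrthogonalEvidence(
                **{c: str(row[c]) for c in cols}
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def write_decisions(decisions: list[TriageDecision], path, seed=None):
    df = pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "discrepancy_opened": int(d.discrepancy_opened),
                "action": d.action,
                "rationale": "|".join(d.rationale),
            }
            for d in decisions
        ],
        columns=["sample_id", "discrepancy_opened", "action", "rationale"],
    )
    _write_tsv(df, path, seed=seed)
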