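"""Feature encoding: variant calls, TPM expression, and sex -> numeric vectors.

A sample is encoded as the concatenation of

* a binary gene-level variant block — entry 1 iff the gene carries at least
  one *reportable* somatic variant (pathogenic / likely pathogenic, VAF >= 5%,
  >= 5 supporting read alignments); allele frequencies themselves are not
  features,
* a normalized expression block — log2(TPM+1), per-platform median-shifted to
  harmonize sequencing platforms, then per-gene z-standardized with parameters
  fitted on training data,
* a single sex entry (male=1, female=0, unknown=0.5).

The production-scale layout is a 227-gene variant panel plus ~10,000
expression genes; both sizes are configurable and tests use small panels.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

CLASSIFICATIONS = ("pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign")
REPORTABLE_CLASSES = frozenset({"pathogenic", "likely_pathogenic"})

#: Reportability thresholds (inclusive): minimum variant allele frequency and
#: minimum number of read alignments supporting the variant.
MIN_VAF = 0.05
MIN_SUPPORT = 5

SEX_CODES = {"male": 1.0, "female": 0.0, "unknown": 0.5}

_SCALE_FLOOR = 1e-8  # constant genes get unit-free zeros instead of blowups


@dataclass(frozen=True)
class VariantRecord:
    sample_id: str
    gene: str
    classification: str
    vaf: float
    support: int

    def __post_init__(self):
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(
                f"unknown variant classification {self.classification!r}; "
                f"expected one of {CLASSIFICATIONS}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.support < 0:
            raise ValueError(f"support {self.support} < 0")


@dataclass(frozen=True)
class ExpressionProfile:
    sample_id: str
    tpm: dict[str, float]
    platform_id: str = "default"

    def __post_init__(self):
        for g, v in self.tpm.items():
            if v < 0:
                raise ValueError(f"negative TPM {v} for gene {g!r} in {self.sample_id}")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    sex: str = "unknown"
    site_class: str = "primary"
    tumor_content: float = 100.0
    submitted_label: str = "<unmapped>"

    def __post_init__(self):
        if self.sex not in SEX_CODES:
            raise ValueError(f"sex must be one of {tuple(SEX_CODES)}, got {self.sex!r}")
        if self.site_class not in ("primary", "metastatic"):
            raise ValueError(f"site_class {self.site_class!r} invalid")
        if not 0.0 <= self.tumor_content <= 100.0:
            raise ValueError(f"tumor_content {self.tumor_content} outside [0, 100]")


@dataclass
class FeatureVector:
    sample_id: str
    values: np.ndarray
    qc_low_tumor_content: bool = False


def filter_reportable_variants(records: list[VariantRecord]) -> list[VariantRecord]:
    """Keep variants that are clinically reportable.

    Reportable = classification in {pathogenic, likely_pathogenic} AND
    VAF >= 5% AND >= 5 supporting alignments (both thresholds inclusive).
    Idempotent by construction.
    """
    return [
        r
        for r in records
        if r.classification in REPORTABLE_CLASSES
        and r.vaf >= MIN_VAF
        and r.support >= MIN_SUPPORT
    ]


def encode_variant_block(records: list[VariantRecord], panel: list[str]) -> np.ndarray:
    """Binary indicator per panel gene: 1 iff >= 1 reportable variant.

    ``records`` must already be filtered; genes outside the panel are ignored
    and repeated hits in one gene collapse to a single 1.
    """
    mutated = {r.gene for r in records}
    return np.array([1.0 if g in mutated else 0.0 for g in panel])


class EncoderModel:
    """Fitted feature layout + expression normalization parameters.

    Expression normalization pipeline, fitted on training profiles:

    1. log2(TPM + 1);
    2. per-platform, per-gene median shift so every platform's gene median
       lands on the pooled (cross-platform) gene median — removes
       multiplicative platform batch factors exactly at the median;
    3. per-gene z-standardization (center, scale) on the shifted values; the
       scale of a constant gene is floored at a tiny epsilon so it encodes
       as zero.

    Genes missing from a profile are imputed as 0 on the standardized scale
    (i.e. at the training mean).
    """

    def __init__(
        self,
        variant_panel: list[str],
        expression_genes: list[str],
        platform_shifts: dict[str, np.ndarray],
        gene_center: np.ndarray,
        gene_scale: np.ndarray,
        min_tumor_content: float = 20.0,
    ):
        if len(set(variant_panel)) != len(variant_panel):
            raise ValueError("variant_panel contains duplicates")
        if len(set(expression_genes)) != len(expression_genes):
            raise ValueError("expression_genes contains duplicates")
        self.variant_panel = list(variant_panel)
        self.expression_genes = list(expression_genes)
        self.platform_shifts = {k: np.asarray(v, float) for k, v in platform_shifts.items()}
        self.gene_center = np.asarray(gene_center, float)
        self.gene_scale = np.maximum(np.asarray(gene_scale, float), _SCALE_FLOOR)
        self.min_tumor_content = float(min_tumor_content)

    @property
    def n_features(self) -> int:
        return len(self.variant_panel) + len(self.expression_genes) + 1

    # ------------------------------------------------------------------- fit

    @classmethod
    def fit(
        cls,
        training_profiles: list[ExpressionProfile],
        variant_panel: list[str],
        n_genes: int = 10_000,
        min_tumor_content: float = 20.0,
    ) -> "EncoderModel":
        """Fit the expression normalizer; see class docstring for the model.

        Gene selection: the ``n_genes`` highest-variance genes of log2(TPM+1)
        across the training profiles (ties broken by gene name for
        determinism).  Requires >= 2 profiles.
        """
        if len(training_profiles) == 0:
            raise ValueError("empty training set")
        if len(training_profiles) < 2:
            raise ValueError("need >= 2 training profiles to fit a normalizer")

        all_genes = sorted({g for p in training_profiles for g in p.tpm})
        gene_idx = {g: i for i, g in enumerate(all_genes)}
        mat = np.zeros((len(training_profiles), len(all_genes)))
        for i, p in enumerate(training_profiles):
            for g, v in p.tpm.items():
                mat[i, gene_idx[g]] = v
        logm = np.log2(mat + 1.0)

        if n_genes > len(all_genes):
            warnings.warn(
                f"requested {n_genes} expression genes but only "
                f"{len(all_genes)} available; using all",
                stacklevel=2,
            )
            n_genes = len(all_genes)
        var = logm.var(axis=0)
        # argsort on (-variance, name) → deterministic top-variance selection
        order = sorted(range(len(all_genes)), key=lambda i: (-var[i], all_genes[i]))
        keep = sorted(order[:n_genes], key=lambda i: all_genes[i])
        genes = [all_genes[i] for i in keep]
        logm = logm[:, keep]

        platforms = np.array([p.platform_id for p in training_profiles])
        pooled_median = np.median(logm, axis=0)
        shifts: dict[str, np.ndarray] = {}
        shifted = logm.copy()
        for plat in sorted(set(platforms)):
            rows = platforms == plat
            shift = pooled_median - np.median(logm[rows], axis=0)
            shifts[plat] = shift
            shifted[rows] += shift

        center = shifted.mean(axis=0)
        scale = shifted.std(axis=0)
        return cls(variant_panel, genes, shifts, center, scale, min_tumor_content)

    # --------------------------------------------------------------- encode

    def normalize_expression(self, profile: ExpressionProfile) -> np.ndarray:
        """Standardized expression vector in the fitted gene order."""
        if profile.platform_id in self.platform_shifts:
            shift = self.platform_shifts[profile.platform_id]
        else:
            log.warning(
                "platform %r unseen during fitting; using identity shift",
                profile.platform_id,
            )
            shift = np.zeros(len(self.expression_genes))
        out = np.zeros(len(self.expression_genes))
        for j, g in enumerate(self.expression_genes):
            if g in profile.tpm:
                x = np.log2(profile.tpm[g] + 1.0) + shift[j]
                out[j] = (x - self.gene_center[j]) / self.gene_scale[j]
            # missing gene → 0 on the standardized scale
        return out

    def encode_sample(
        self,
        meta: SampleMeta,
        records: list[VariantRecord],
        profile: ExpressionProfile,
    ) -> FeatureVector:
        """Full feature vector: [variant block | expression block | sex].

        ``records`` may be unfiltered; reportability filtering is applied
        here so the encoding contract is self-contained.  A QC flag (not an
        error) is set when tumor content is below the configured minimum.
        """
        if meta.sample_id != profile.sample_id:
            raise ValueError(
                f"sample_id mismatch: meta {meta.sample_id!r} vs "
                f"expression {profile.sample_id!r}"
            )
        own = [r for r in records if r.sample_id == meta.sample_id]
        if len(own) != len(records) and records:
            bad = {r.sample_id for r in records} - {meta.sample_id}
            raise ValueError(f"variant records for foreign samples: {sorted(bad)}")
        vblock = encode_variant_block(filter_reportable_variants(own), self.variant_panel)
        eblock = self.normalize_expression(profile)
        sex = SEX_CODES[meta.sex]
        flag = meta.tumor_content < self.min_tumor_content
        if flag:
            log.warning(
                "sample %s: tumor content %.1f%% below minimum %.1f%%",
                meta.sample_id,
                meta.tumor_content,
                self.min_tumor_content,
            )
        return FeatureVector(
            sample_id=meta.sample_id,
            values=np.concatenate([vblock, eblock, [sex]]),
            qc_low_tumor_content=flag,
        )

    # -------------------------------------------------------------- persist

    def to_dict(self) -> dict:
        return {
            "variant_panel": self.variant_panel,
            "expression_genes": self.expression_genes,
            "platform_shifts": {k: v.tolist() for k, v in self.platform_shifts.items()},
            "gene_center": self.gene_center.tolist(),
            "gene_scale": self.gene_scale.tolist(),
            "min_tumor_content": self.min_tumor_content,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderModel":
        return cls(
            d["variant_panel"],
            d["expression_genes"],
            {k: np.array(v) for k, v in d["platform_shifts"].items()},
            np.array(d["gene_center"]),
            np.array(d["gene_scale"]),
            d.get("min_tumor_content", 20.0),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "EncoderModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# Spec-level alias: fitting the expression side of the encoder.
fit_expression_normalizer = EncoderModel.fit
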