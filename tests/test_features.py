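"""Variant filtering, feature layout, and expression normalization."""

import numpy as np
import pytest

from oncotoc import (
    EncoderModel,
    ExpressionProfile,
    SampleMeta,
    VariantRecord,
    encode_variant_block,
    filter_reportable_variants,
)


def v(gene="KRAS", cls="pathogenic", vaf=0.5, support=100, sid="s1"):
    return VariantRecord(sid, gene, cls, vaf, support)


class TestReportabilityFilter:
    @pytest.mark.parametrize(
        "cls, vaf, support, kept",
        [
            ("pathogenic", 0.50, 100, True),
            ("likely_pathogenic", 0.50, 100, True),
            ("vus", 0.50, 100, False),
            ("likely_benign", 0.50, 100, False),
            ("benign", 0.50, 100, False),
            ("pathogenic", 0.04, 100, False),  # below 5% VAF
            ("pathogenic", 0.05, 100, True),  # threshold is inclusive
            ("pathogenic", 0.50, 4, False),  # fewer than 5 alignments
            ("pathogenic", 0.50, 5, True),  # inclusive
            ("pathogenic", 0.05, 5, True),  # both exactly at threshold
        ],
    )
    def test_thresholds(self, cls, vaf, support, kept):
        records = [v(cls=cls, vaf=vaf, support=support)]
        assert len(filter_reportable_variants(records)) == int(kept)

    def test_idempotent(self):
        records = [v(), v(cls="vus"), v(vaf=0.01), v(support=2)]
        once = filter_reportable_variants(records)
        assert filter_reportable_variants(once) == once

    def test_malformed_classification_rejected(self):
        with pytest.raises(ValueError, match="classification"):
            v(cls="Pathogenic")  # case-sensitive enum


class TestVariantBlock:
    PANEL = ["BRAF", "EGFR", "KRAS", "TP53"]

    def test_empty_and_off_panel(self):
        assert encode_variant_block([], self.PANEL).tolist() == [0, 0, 0, 0]
        assert encode_variant_block([v(gene="MYC")], self.PANEL).tolist() == [0, 0, 0, 0]

    def test_matches_set_membership_oracle(self):
        """Indicator encoding equals brute-force set membership, including
        idempotence under repeated hits in one gene."""
        rng = np.random.default_rng(42)
        genes = self.PANEL + ["MYC", "ALK"]
        for _ in range(50):
            records = [
                v(gene=genes[i]) for i in rng.integers(0, len(genes), size=rng.integers(0, 8))
            ]
            expected = [1.0 if any(r.gene == g for r in records) else 0.0 for g in self.PANEL]
            assert encode_variant_block(records, self.PANEL).tolist() == expected

    def test_order_invariance(self):
        records = [v(gene="KRAS"), v(gene="BRAF"), v(gene="KRAS")]
        fwd = encode_variant_block(records, self.PANEL)
        rev = encode_variant_block(records[::-1], self.PANEL)
        assert (fwd == rev).all()


def profiles_with_batch_factor(factor=3.0, n=40, n_genes=20, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(n_genes)]
    out = []
    for i in range(n):
        base = rng.lognormal(3, 1, size=n_genes)
        plat = "P1" if i % 2 == 0 else "P2"
        tpm = base * (factor if plat == "P2" else 1.0)
        out.append(ExpressionProfile(f"s{i}", dict(zip(genes, tpm)), plat))
    return out


class TestNormalizer:
    def test_platform_median_shift_removes_batch_factor(self):
        """After fitting, per-platform per-gene medians of the shifted
        log-expression agree across platforms within 1e-6."""
        profiles = profiles_with_batch_factor(factor=3.0)
        enc = EncoderModel.fit(profiles, ["KRAS"], n_genes=20)
        shifted = {"P1": [], "P2": []}
        for p in profiles:
            x = np.array([np.log2(p.tpm[g] + 1) for g in enc.expression_genes])
            shifted[p.platform_id].append(x + enc.platform_shifts[p.platform_id])
        med1 = np.median(np.array(shifted["P1"]), axis=0)
        med2 = np.median(np.array(shifted["P2"]), axis=0)
        assert np.abs(med1 - med2).max() < 1e-6

    def test_constant_genes_encode_to_zero(self):
        tpm = {"G0": 5.0, "G1": 7.0}
        profiles = [ExpressionProfile(f"s{i}", dict(tpm), "P1") for i in range(4)]
        enc = EncoderModel.fit(profiles, [], n_genes=2)
        out = enc.normalize_expression(profiles[0])
        assert np.allclose(out, 0.0)

    def test_n_genes_capped_with_warning(self):
        profiles = profiles_with_batch_factor(n=4, n_genes=10)
        with pytest.warns(UserWarning, match="only 10 available"):
            enc = EncoderModel.fit(profiles, [], n_genes=500)
        assert len(enc.expression_genes) == 10

    def test_top_variance_selection(self):
        rng = np.random.default_rng(1)
        profiles = []
        for i in range(30):
            profiles.append(
                ExpressionProfile(
                    f"s{i}",
                    {"FLAT": 10.0, "VAR1": float(rng.lognormal(3, 2)), "VAR2": float(rng.lognormal(3, 1.5))},
                    "P1",
                )
            )
        enc = EncoderModel.fit(profiles, [], n_genes=2)
        assert set(enc.expression_genes) == {"VAR1", "VAR2"}

    def test_too_few_profiles_rejected(self):
        with pytest.raises(ValueError):
            EncoderModel.fit([], [], n_genes=5)
        with pytest.raises(ValueError):
            EncoderModel.fit([ExpressionProfile("s0", {"G": 1.0})], [], n_genes=1)


class TestEncodeSample:
    @pytest.fixture
    def enc(self):
        return EncoderModel.fit(profiles_with_batch_factor(), ["BRAF", "KRAS"], n_genes=20)

    def test_layout_and_sex_codes(self, enc):
        profile = profiles_with_batch_factor()[0]
        for sex, code in [("male", 1.0), ("female", 0.0), ("unknown", 0.5)]:
            meta = SampleMeta("s0", sex=sex)
            fv = enc.encode_sample(meta, [v(sid="s0", gene="KRAS")], profile)
            assert len(fv.values) == 2 + 20 + 1 == enc.n_features
            assert fv.values[-1] == code
            assert fv.values[:2].tolist() == [0.0, 1.0]  # BRAF, KRAS

    def test_unfiltered_records_are_filtered_internally(self, enc):
        profile = profiles_with_batch_factor()[0]
        fv = enc.encode_sample(
            SampleMeta("s0"), [v(sid="s0", gene="KRAS", vaf=0.01)], profile
        )
        assert fv.values[:2].tolist() == [0.0, 0.0]

    def test_low_tumor_content_flags_not_rejects(self, enc):
        profile = profiles_with_batch_factor()[0]
        fv = enc.encode_sample(SampleMeta("s0", tumor_content=15.0), [], profile)
        assert fv.qc_low_tumor_content
        assert enc.encode_sample(SampleMeta("s0", tumor_content=20.0), [], profile).qc_low_tumor_content is False

    def test_sample_id_mismatch_rejected(self, enc):
        profile = profiles_with_batch_factor()[0]
        with pytest.raises(ValueError, match="mismatch"):
            enc.encode_sample(SampleMeta("other"), [], profile)
        with pytest.raises(ValueError, match="foreign"):
            enc.encode_sample(SampleMeta("s0"), [v(sid="s9")], profile)

    def test_tpm_order_invariance(self, enc):
        p = profiles_with_batch_factor()[0]
        reordered = ExpressionProfile(
            p.sample_id, dict(reversed(list(p.tpm.items()))), p.platform_id
        )
        a = enc.encode_sample(SampleMeta("s0"), [], p)
        b = enc.encode_sample(SampleMeta("s0"), [], reordered)
        assert (a.values == b.values).all()

    def test_unknown_platform_identity_params(self, enc):
        p0 = profiles_with_batch_factor()[0]
        alien = ExpressionProfile(p0.sample_id, p0.tpm, "P99")
        fv = enc.encode_sample(SampleMeta("s0"), [], alien)
        assert np.isfinite(fv.values).all()

    def test_round_trip_json(self, enc, tmp_path):
        enc.save(tmp_path / "enc.json")
        enc2 = EncoderModel.load(tmp_path / "enc.json")
        p = profiles_with_batch_factor()[0]
        a = enc.encode_sample(SampleMeta("s0"), [], p)
        b = enc2.encode_sample(SampleMeta("s0"), [], p)
        assert np.allclose(a.values, b.values)


def test_metadata_validation():
    with pytest.raises(ValueError):
        SampleMeta("s", sex="M")
    with pytest.raises(ValueError):
        SampleMeta("s", tumor_content=101)
    with pytest.raises(ValueError):
        SampleMeta("s", site_class="met")
    with pytest.raises(ValueError):
        ExpressionProfile("s", {"G": -1.0})
    with pytest.raises(ValueError):
        VariantRecord("s", "G", "pathogenic", 1.5, 10)
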