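"""Allelic imbalance statistics, reproducibility score, and cohort calls."""

import numpy as np
import pytest

from chromdiff.allelic import (ALLELIC, HET_NOT_ALLELIC, NOT_CANDIDATE,
                               AllelicCountRecord, aggregate_variants,
                               call_allelic, candidate_variants, imbalance,
                               ars_score, pooled_imbalance, score_records,
                               summarize)
from chromdiff.core import (HET, HOM_ALT, HOM_REF, ConfigurationError,
                            GenomicInterval, PeakSet, VariantRecord)


def _variant(vid, pos, genotypes, chrom="chr1"):
    return VariantRecord(chrom, pos, vid, "A", "G", genotypes)


class TestCandidateVariants:
    @pytest.fixture
    def peaks(self):
        return PeakSet("s1", "ATAC", "case",
                       [GenomicInterval("chr1", 100, 600, name="p0"),
                        GenomicInterval("chr1", 1000, 1500, name="p1")])

    def test_het_in_peak_required(self, peaks):
        variants = [
            _variant("in_het", 200, {"s1": HET}),          # candidate
            _variant("in_homref", 300, {"s1": HOM_REF}),   # not het
            _variant("in_homalt", 400, {"s1": HOM_ALT}),   # not het
            _variant("out_het", 800, {"s1": HET}),         # outside peaks
        ]
        out = candidate_variants(variants, peaks, "s1")
        assert [v.id for v in out] == ["in_het"]

    def test_constructed_count(self, peaks):
        # 10 variants, exactly 4 het-in-peak by construction
        variants = []
        for k in range(10):
            pos = 150 + 40 * k if k < 6 else 2000 + 10 * k  # 6 in, 4 out
            gt = HET if k in (0, 1, 2, 3, 8, 9) else HOM_REF
            variants.append(_variant(f"v{k}", pos, {"s1": gt}))
        assert len(candidate_variants(variants, peaks, "s1")) == 4

    def test_unknown_subject_rejected(self, peaks):
        with pytest.raises(ConfigurationError):
            candidate_variants([_variant("v", 200, {"s1": HET})], peaks, "s2")


class TestImbalance:
    def test_balanced(self):
        strong, p_hat, m, p = imbalance(5, 5)
        assert (strong, p_hat, m, p) == ("ref", 0.5, 0.0, 1.0)

    def test_aggregated_printed_counts(self):
        """112 vs 10 reads pooled across subjects: strong-allele fraction
        ~0.918, consistent with per-subject fractions of 0.85-1.00."""
        strong, p_hat, m, p = imbalance(112, 10)
        assert strong == "ref"
        assert p_hat == pytest.approx(112 / 122, rel=1e-12)
        assert 0.85 <= p_hat <= 1.0
        assert p < 1e-15

    def test_total_skew_closed_form(self):
        _, _, _, p = imbalance(20, 0)
        assert p == pytest.approx(min(1.0, 2 * 0.5**20), rel=1e-9)

    def test_zero_reads_undefined(self):
        with pytest.raises(ValueError):
            imbalance(0, 0)

    def test_allele_swap_symmetry(self, rng):
        for _ in range(20):
            a, b = int(rng.integers(0, 50)), int(rng.integers(1, 50))
            _, p1, m1, bp1 = imbalance(a, b)
            _, p2, m2, bp2 = imbalance(b, a)
            assert (p1, m1) == (p2, m2)
            assert bp1 == pytest.approx(bp2, rel=1e-12)


class TestArsScore:
    def test_zero_imbalance_gives_zero(self):
        for n in (1, 10, 1000):
            assert ars_score(n, 0.0) == 0.0

    def test_formula_arithmetic(self):
        # n=20, p_hat=0.95 -> m=0.9, depth=log10(21)/2, ars ~ 0.595
        ars = ars_score(20, 0.9)
        assert ars == pytest.approx(0.9 * np.log10(21) / 2, rel=1e-12)
        assert ars == pytest.approx(0.595, abs=0.002)
        assert ars >= 0.4
        # n=4, p_hat=1.0 -> depth-gated below threshold
        ars_low = ars_score(4, 1.0)
        assert ars_low == pytest.approx(np.log10(5) / 2, rel=1e-12)
        assert ars_low < 0.4

    def test_depth_saturates_at_one(self):
        assert ars_score(1_000_000, 1.0) == 1.0

    def test_monotone_grid(self):
        depths = [1, 3, 10, 30, 100, 300, 1000]
        ms = np.linspace(0, 1, 11)
        grid = np.array([[ars_score(n, m) for n in depths] for m in ms])
        assert (np.diff(grid, axis=0) >= -1e-12).all()  # in m
        assert (np.diff(grid, axis=1) >= -1e-12).all()  # in depth


class TestCallAllelic:
    def _rec(self, n_ref, n_alt):
        return AllelicCountRecord("v", "s", "ATAC", n_ref, n_alt)

    def test_threshold_inclusive_at_exactly_0_4(self):
        rec = self._rec(1, 1)
        rec.ars = 0.4
        assert call_allelic([rec])[0].is_allelic
        rec.ars = 0.39
        assert not call_allelic([rec])[0].is_allelic

    def test_null_false_positive_rate(self):
        """Balanced variants (bias 0.5, mean depth 30): <= 5% called allelic
        over 10^4 simulated variants."""
        gen = np.random.default_rng(17)
        records = []
        for k in range(10_000):
            depth = max(1, int(gen.poisson(30)))
            n_alt = int(gen.binomial(depth, 0.5))
            records.append(self._rec(depth - n_alt, n_alt))
        call_allelic(score_records(records))
        rate = np.mean([r.is_allelic for r in records])
        assert rate <= 0.05

    def test_sensitivity_on_planted_bias(self):
        """Bias 0.85 at depth >= 30: sensitivity >= 0.8."""
        gen = np.random.default_rng(23)
        records = []
        for k in range(5_000):
            depth = 30 + int(gen.poisson(5))
            n_alt = int(gen.binomial(depth, 0.85))
            records.append(self._rec(depth - n_alt, n_alt))
        call_allelic(score_records(records))
        assert np.mean([r.is_allelic for r in records]) >= 0.8

    def test_cohort_truth_recovery(self, small_cohort):
        """On the generated cohort: sensitivity >= 0.8 on imbalanced variants
        (bias 0.85, mean depth 30), false-positive rate <= 5% on balanced."""
        truth = small_cohort.truth.variant_imbalance
        records = [AllelicCountRecord(r["variant_id"], r["subject_id"],
                                      r["assay"], r["n_ref"], r["n_alt"])
                   for r in small_cohort.allelic_counts if r["n_ref"] + r["n_alt"]]
        call_allelic(score_records(records))
        flags = np.array([r.is_allelic for r in records])
        imb = np.array([truth[r.variant_id][0] for r in records])
        assert flags[imb].mean() >= 0.8
        assert flags[~imb].mean() <= 0.05


class TestAggregate:
    def test_matrix_cells(self):
        recs = [AllelicCountRecord("v1", "s1", "ATAC", 19, 1),
                AllelicCountRecord("v1", "s2", "ATAC", 10, 10),
                AllelicCountRecord("v2", "s2", "ATAC", 30, 2)]
        call_allelic(score_records(recs))
        m = aggregate_variants(recs, subjects=["s1", "s2", "s3"])
        assert m.loc["v1", "s1"] == ALLELIC
        assert m.loc["v1", "s2"] == HET_NOT_ALLELIC
        assert m.loc["v1", "s3"] == NOT_CANDIDATE
        assert m.loc["v2", "s1"] == NOT_CANDIDATE
        summary = summarize(m)
        assert summary.loc["v1", "n_allelic_subjects"] == 1
        assert summary.loc["v1", "n_opportunities"] == 2
        assert summary["n_opportunities"].sum() == 3

    def test_empty_records_give_empty_matrix(self):
        m = aggregate_variants([], subjects=["s1"])
        assert m.shape == (0, 1)

    def test_pooled_imbalance_sums_reads(self):
        recs = [AllelicCountRecord("v", "s1", "ATAC", 60, 6),
                AllelicCountRecord("v", "s2", "ATAC", 52, 4)]
        n_ref, n_alt, p_hat = pooled_imbalance(recs)
        assert (n_ref, n_alt) == (112, 10)
        assert p_hat == pytest.approx(112 / 122)
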