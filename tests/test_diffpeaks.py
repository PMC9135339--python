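"""Pairwise differential analysis: matching, normalization, testing, labels."""

import math

import numpy as np
import pytest

from chromdiff.core import ConfigurationError, GenomicInterval, PeakSet, intersect
from chromdiff.diffpeaks import (CASE_SPECIFIC, CONTROL_SPECIFIC, SHARED,
                                 MAPoint, PairwiseDifferentialResult, classify,
                                 differential_pvalue, frip, ma_normalize,
                                 ma_values, match_peaks, pairwise_differential)


def _peakset(subject, cond, spans, counts):
    ivs = [GenomicInterval("chr1", s, e, name=f"{subject}_{k}")
           for k, (s, e) in enumerate(spans)]
    return PeakSet(subject, "ATAC", cond, ivs, np.asarray(counts))


class TestMatchPeaks:
    def test_disjoint_and_identical(self):
        a = _peakset("a", "case", [(0, 100), (200, 300)], [5, 5])
        b = _peakset("b", "control", [(400, 500), (600, 700)], [5, 5])
        common, ua, ub = match_peaks(a, b)
        assert (common, ua, ub) == ([], [0, 1], [0, 1])
        common, ua, ub = match_peaks(a, a)
        assert common == [(0, 0), (1, 1)] and ua == [] and ub == []

    def test_missing_counts_rejected(self):
        a = _peakset("a", "case", [(0, 100)], [5])
        b = PeakSet("b", "ATAC", "control", [GenomicInterval("chr1", 0, 100)])
        with pytest.raises(ConfigurationError):
            match_peaks(a, b)

    def test_engineered_overlaps_match_intersect_oracle(self, rng):
        starts_a = rng.choice(10_000, size=100, replace=False) * 100
        spans_a = [(int(s), int(s) + 80) for s in sorted(starts_a)]
        # 30 engineered overlaps, the rest displaced far away
        spans_b = [(s + 40, s + 120) for s, _ in spans_a[:30]]
        spans_b += [(s + 2_000_000, s + 2_000_080) for s, _ in spans_a[30:]]
        a = _peakset("a", "case", spans_a, np.ones(100))
        b = _peakset("b", "control", sorted(spans_b), np.ones(100))
        common, ua, ub = match_peaks(a, b)
        assert len(common) == 30
        oracle_pairs = set(intersect(a.intervals, b.intervals))
        assert set(common) <= oracle_pairs
        assert len(common) + len(ua) == 100 and len(common) + len(ub) == 100

    def test_chain_resolved_to_best_overlap(self):
        # one control peak overlapping two case peaks: larger overlap wins
        a = _peakset("a", "case", [(0, 100), (150, 400)], [1, 1])
        b = _peakset("b", "control", [(90, 200)], [1])
        common, ua, ub = match_peaks(a, b)
        assert common == [(1, 0)]  # 50 bp beats 10 bp
        assert ua == [0] and ub == []


class TestMANormalize:
    def test_global_scaling_recovered(self):
        """x_ctrl = 4 x_case: baseline a ~ -2, b ~ 0, all M_norm ~ 0."""
        x_case = np.arange(20, 220, 10, dtype=float)
        M, A = ma_values(x_case, 4 * x_case)
        a, b = ma_normalize(M, A)
        assert a == pytest.approx(-2.0, abs=0.05)
        assert b == pytest.approx(0.0, abs=0.02)
        assert np.allclose(M - (a + b * A), 0.0, atol=0.1)

    def test_identity_when_equal(self):
        x = np.arange(10, 110, 10, dtype=float)
        M, A = ma_values(x, x)
        a, b = ma_normalize(M, A)
        assert a == pytest.approx(0.0, abs=1e-9)
        assert b == pytest.approx(0.0, abs=1e-9)

    def test_too_few_common_peaks_raises(self):
        with pytest.raises(ConfigurationError):
            ma_normalize(np.zeros(5), np.zeros(5))

    def test_median_m_norm_near_zero_on_cohort(self, default_cohort):
        case = default_cohort.peaksets["AD1"]
        ctrl = default_cohort.peaksets["CTL1"]
        res = pairwise_differential(case, ctrl, "pair1")
        m_norm = [p.M_norm for p in res.points if p.origin == "common"]
        assert abs(np.median(m_norm)) < 0.05


class TestDifferentialPvalue:
    def test_equal_counts_equal_libraries(self):
        for x in (0, 1, 5, 50):
            assert differential_pvalue(x, x, 1e6, 1e6) >= 0.5

    def test_symmetry_with_equal_libraries(self):
        assert differential_pvalue(7, 19, 1e6, 1e6) == pytest.approx(
            differential_pvalue(19, 7, 1e6, 1e6), rel=1e-12)

    def test_twenty_vs_zero_matches_direct_summation_oracle(self):
        """Posterior-predictive tails summed by hand for x=20, y=0 in both
        conditioning orientations (the pinned symmetrized statistic)."""
        x, y = 20, 0

        def pmf(a, k):  # P(other = k | observed a), equal libraries
            return math.comb(a + k, k) / 2 ** (a + k + 1)

        # orientation 1: condition on x=20, observe y=0
        lower1 = sum(pmf(x, k) for k in range(y + 1))
        upper1 = 1.0 - sum(pmf(x, k) for k in range(y))
        p1 = min(1.0, 2 * min(lower1, upper1))
        # orientation 2: condition on y=0, observe x=20
        lower2 = sum(pmf(y, k) for k in range(x + 1))
        upper2 = 1.0 - sum(pmf(y, k) for k in range(x))
        p2 = min(1.0, 2 * min(lower2, upper2))
        expected = min(1.0, 0.5 * (p1 + p2))
        assert differential_pvalue(x, y, 1e6, 1e6) == pytest.approx(expected,
                                                                    rel=1e-10)

    def test_monotone_in_divergence(self):
        assert differential_pvalue(10, 12, 1e6, 1e6) > differential_pvalue(
            10, 120, 1e6, 1e6)

    def test_library_scaling_restores_null(self):
        # doubling the control library doubles expected control counts
        p_unscaled = differential_pvalue(50, 100, 1e6, 1e6)
        p_scaled = differential_pvalue(50, 100, 1e6, 2e6)
        assert p_scaled > p_unscaled


class TestClassify:
    def _result(self, m_norm, p):
        pt = MAPoint("pk", "chr1", 0, 100, 10, 10, M_norm=m_norm, p_value=p)
        return PairwiseDifferentialResult("pair1", [pt])

    @pytest.mark.parametrize("m_norm,p,expected", [
        (0.0, 1e-9, SHARED),                  # no fold change
        (1.0, 0.01, CASE_SPECIFIC),           # 2-fold, significant
        (1.0, 0.2, SHARED),                   # p gate blocks
        (-1.0, 0.01, CONTROL_SPECIFIC),
        (np.log2(1.5), 0.01, SHARED),         # strict inequality at 1.5
        (np.log2(1.51), 0.01, CASE_SPECIFIC),
    ])
    def test_threshold_rules(self, m_norm, p, expected):
        res = classify(self._result(m_norm, p))
        assert res.points[0].label == expected


class TestPairwiseProperties:
    def test_swap_antisymmetry_exact(self, small_cohort):
        case = small_cohort.peaksets["AD1"]
        ctrl = small_cohort.peaksets["CTL1"]
        fwd = pairwise_differential(case, ctrl, "f")
        rev = pairwise_differential(ctrl, case, "r")
        swap = {CASE_SPECIFIC: CONTROL_SPECIFIC,
                CONTROL_SPECIFIC: CASE_SPECIFIC, SHARED: SHARED}
        fwd_labels = {p.peak_id: p.label for p in fwd.points}
        rev_labels = {p.peak_id: p.label for p in rev.points}
        assert set(fwd_labels) == set(rev_labels)
        for pid, lab in fwd_labels.items():
            assert rev_labels[pid] == swap[lab]

    def test_recall_of_planted_specific_peaks(self, default_cohort):
        """>= 90% of 3-fold planted case-specific peaks recovered per pair."""
        truth = default_cohort.truth.peak_labels
        planted = {k for k, v in truth.items() if v == "case_specific"}
        case_id, ctrl_id = default_cohort.pairs[0]
        res = pairwise_differential(default_cohort.peaksets[case_id],
                                    default_cohort.peaksets[ctrl_id], "pair1")
        labels = {p.peak_id: p.label for p in res.points}
        recall = sum(labels[k] == CASE_SPECIFIC for k in planted) / len(planted)
        assert recall >= 0.90

    def test_false_positive_ceiling_under_null(self, null_cohort):
        """<= 7% specific calls when nothing is planted."""
        case_id, ctrl_id = null_cohort.pairs[0]
        res = pairwise_differential(null_cohort.peaksets[case_id],
                                    null_cohort.peaksets[ctrl_id], "pair1")
        counts = res.label_counts()
        frac = (counts[CASE_SPECIFIC] + counts[CONTROL_SPECIFIC]) / len(res.points)
        assert frac <= 0.07

    def test_shared_fraction_in_reported_regime(self, default_cohort):
        """With <= 10% planted specific peaks the shared fraction falls in
        the 85.9-96.0% regime reported for real matched pairs."""
        for case_id, ctrl_id in default_cohort.pairs[:2]:
            res = pairwise_differential(default_cohort.peaksets[case_id],
                                        default_cohort.peaksets[ctrl_id], "p")
            shared = res.label_counts()[SHARED] / len(res.points)
            assert 0.859 <= shared <= 0.98


class TestFrip:
    def _reads(self, positions):
        return [GenomicInterval("chr1", p, p + 50) for p in positions]

    def test_all_inside_and_no_peaks(self):
        peaks = PeakSet("s", "ATAC", "case",
                        [GenomicInterval("chr1", 0, 1000)], np.array([1]))
        assert frip(self._reads([10, 500, 900]), peaks) == 1.0
        empty = PeakSet("s", "ATAC", "case", [], np.array([]))
        assert frip(self._reads([10]), empty) == 0.0
        with pytest.raises(ValueError):
            frip([], peaks)

    def test_planted_fraction_recovered_exactly(self, rng):
        peaks = PeakSet("s", "ATAC", "case",
                        [GenomicInterval("chr1", k * 10_000, k * 10_000 + 1000)
                         for k in range(10)], np.ones(10))
        inside = [int(k * 10_000 + rng.integers(900)) for k in rng.integers(0, 10, 400)]
        outside = [int(5_000_000 + i * 100) for i in range(600)]
        assert frip(self._reads(inside + outside), peaks) == pytest.approx(0.40)
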