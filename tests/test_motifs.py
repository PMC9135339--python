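"""PWM parsing, scanning, exact threshold DP, and Fisher enrichment."""

import itertools

import numpy as np
import pytest
from scipy import stats

from chromdiff.motifs import (PWM, hit_threshold, motif_enrichment,
                              peak_contains_hit, pooled_background,
                              pwm_from_counts, read_pwm, score_distribution,
                              score_positions)
from chromdiff.simulate import DEFAULT_MOTIF_COUNTS

REVCOMP = str.maketrans("ACGT", "TGCA")


def _rc(seq):
    return seq.translate(REVCOMP)[::-1]


def _random_pwm(rng, width, conc=0.3):
    return PWM("rand", rng.dirichlet(np.full(4, conc), size=width),
               np.full(4, 0.25))


class TestReadPwm:
    def test_uniform_matrix(self, tmp_path):
        p = tmp_path / "u.pfm"
        p.write_text(">uni\n" + "\n".join("1\t1\t1\t1" for _ in range(6)) + "\n")
        pwm = read_pwm(p)
        assert np.allclose(pwm.matrix, 0.25)

    def test_pseudocount_normalization(self, tmp_path):
        p = tmp_path / "c.pfm"
        p.write_text("\n".join("10\t0\t0\t0" for _ in range(4)) + "\n")
        pwm = read_pwm(p)
        assert pwm.matrix[0, 0] == pytest.approx(10.001 / 10.004, rel=1e-9)
        assert pwm.matrix[0, 1] == pytest.approx(0.001 / 10.004, rel=1e-9)

    def test_cisbp_and_jaspar_dialects_agree(self, tmp_path):
        counts = DEFAULT_MOTIF_COUNTS
        cisbp = tmp_path / "cisbp.txt"
        cisbp.write_text("Pos\tA\tC\tG\tT\n" + "\n".join(
            f"{j+1}\t" + "\t".join(f"{v:g}" for v in row)
            for j, row in enumerate(counts)) + "\n")
        jaspar = tmp_path / "jaspar.txt"
        jaspar.write_text(">m1\n" + "\n".join(
            f"{b} [ " + " ".join(f"{v:g}" for v in counts[:, i]) + " ]"
            for i, b in enumerate("ACGT")) + "\n")
        assert np.allclose(read_pwm(cisbp).matrix, read_pwm(jaspar).matrix)

    def test_nonpositive_row_rejected(self):
        bad = np.array([[0, 0, 0, 0]] * 4, dtype=float)
        with pytest.raises(ValueError):
            pwm_from_counts("bad", bad)


class TestScorePositions:
    def test_uniform_pwm_scores_zero(self):
        pwm = PWM("u", np.full((5, 4), 0.25), np.full(4, 0.25))
        plus, minus = score_positions(pwm, "ACGTACGTAC")
        assert np.allclose(plus, 0) and np.allclose(minus, 0)

    def test_strand_symmetry_exact(self, rng):
        pwm = _random_pwm(rng, 6)
        seq = "".join(rng.choice(list("ACGT"), 40))
        plus, minus = score_positions(pwm, seq)
        rc_plus, rc_minus = score_positions(pwm, _rc(seq))
        assert np.allclose(plus, rc_minus[::-1])
        assert np.allclose(minus, rc_plus[::-1])

    def test_n_windows_score_negative_infinity(self):
        pwm = PWM("u", np.full((4, 4), 0.25), np.full(4, 0.25))
        plus, _ = score_positions(pwm, "ACGNACGT")
        assert np.isneginf(plus[:4]).all() and np.isfinite(plus[4])

    def test_short_sequence_gives_empty(self):
        pwm = PWM("u", np.full((6, 4), 0.25), np.full(4, 0.25))
        plus, minus = score_positions(pwm, "ACG")
        assert len(plus) == 0 and len(minus) == 0

    def test_consensus_attains_unique_maximum_over_all_8mers(self, rng):
        """Exhaustive 4^8 enumeration: the consensus sequence scores highest."""
        pwm = _random_pwm(rng, 8, conc=0.2)
        lo = pwm.log_odds()
        seqs = np.array(list(itertools.product(range(4), repeat=8)))
        scores = lo[np.arange(8), seqs].sum(axis=1)
        best = seqs[np.argmax(scores)]
        assert "".join("ACGT"[i] for i in best) == pwm.consensus


class TestHitThreshold:
    @pytest.mark.parametrize("width", [4, 5, 6])
    def test_dp_equals_exhaustive_enumeration(self, width, rng):
        """DP tail probabilities equal brute-force enumeration of all 4^w
        windows, hence identical thresholds at any alpha."""
        pwm = _random_pwm(rng, width)
        lo = pwm.log_odds()
        seqs = np.array(list(itertools.product(range(4), repeat=width)))
        scores = np.sort(lo[np.arange(width), seqs].sum(axis=1))
        dp_scores, dp_probs = score_distribution(pwm)
        # every enumerated score appears in the DP support with prob 4^-w each
        for alpha in (0.3, 0.05, 1e-3, 1e-4):
            t_dp = hit_threshold(pwm, alpha)
            tail = (scores >= t_dp - 1e-9).mean()
            assert tail <= alpha
            # next-lower achievable score would exceed alpha
            below = scores[scores < t_dp - 1e-9]
            if len(below):
                t_next = below.max()
                assert (scores >= t_next - 1e-9).mean() > alpha
        assert np.isclose(dp_probs.sum(), 1.0)

    def test_alpha_bounds_enforced(self, rng):
        pwm = _random_pwm(rng, 4)
        with pytest.raises(ValueError):
            hit_threshold(pwm, 0.7)

    def test_monte_carlo_hit_rate_matches_dp_tail(self, rng):
        """Hit rate on random background positions is within 3 sd of the
        exact DP tail probability at the returned cutoff."""
        pwm = _random_pwm(rng, 10, conc=0.2)
        cutoff = hit_threshold(pwm, 1e-4)
        scores, probs = score_distribution(pwm)
        exact_tail = probs[scores >= cutoff - 1e-9].sum()
        n = 300_000
        seq = "".join(rng.choice(list("ACGT"), n + 9))
        plus, _ = score_positions(pwm, seq)
        rate = (plus >= cutoff).mean()
        sd = np.sqrt(exact_tail * (1 - exact_tail) / n)
        assert abs(rate - exact_tail) < 3.5 * sd
        assert exact_tail <= 1e-4


class TestMotifEnrichment:
    def test_identical_sets_not_enriched(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(40)]
        pwm = _random_pwm(rng, 6)
        enr = motif_enrichment(seqs, seqs, pwm)
        assert enr.fg_hit_fraction == enr.bg_hit_fraction
        assert enr.p_value >= 0.5

    def test_fisher_p_equals_hypergeometric_tail_oracle(self, rng):
        """2x2 table (17,83 / 4,96), mirroring the ~17% vs ~4% contrast."""
        seqs_fg = ["A" * 30] * 100
        table = [[17, 83], [4, 96]]
        _, p_fisher = stats.fisher_exact(table, alternative="greater")
        # direct hypergeometric tail: P(X >= 17 | N=200, K=21, n=100)
        p_oracle = stats.hypergeom.sf(16, 200, 21, 100)
        assert p_fisher == pytest.approx(p_oracle, rel=1e-9)

    def test_enrichment_p_monotone_in_foreground_hits(self):
        p_prev = 1.1
        for fg_hits in (5, 10, 20, 40):
            _, p = stats.fisher_exact([[fg_hits, 100 - fg_hits], [5, 95]],
                                      alternative="greater")
            assert p < p_prev
            p_prev = p

    def test_planted_rate_recovered_with_significance(self):
        """Plant rate 0.3 in case-specific peaks vs 0.01 background: the
        foreground fraction is recovered within +/-0.05 and p < 1e-6."""
        from chromdiff.simulate import CohortConfig, generate_cohort

        b = generate_cohort(CohortConfig(seed=2, n_shared_peaks=300,
                                         n_case_specific=300, n_pairs=1,
                                         n_genes=0, n_up_genes=0,
                                         n_down_genes=0,
                                         n_het_variants_in_peaks=0))
        pwm = pwm_from_counts("m", DEFAULT_MOTIF_COUNTS)
        labels = b.truth.peak_labels
        fg = [b.peak_sequence(iv) for iv in b.base_peaks
              if labels[iv.name] == "case_specific"]
        bg = [b.peak_sequence(iv) for iv in b.base_peaks
              if labels[iv.name] == "shared"]
        enr = motif_enrichment(fg, bg, pwm, alpha=1e-5)
        assert enr.fg_hit_fraction == pytest.approx(0.3, abs=0.05)
        assert enr.p_value < 1e-6

    def test_case_biased_planting_gives_case_direction(self, small_cohort):
        pwm = pwm_from_counts("m", DEFAULT_MOTIF_COUNTS)
        labels = small_cohort.truth.peak_labels
        fg = [small_cohort.peak_sequence(iv) for iv in small_cohort.base_peaks
              if labels[iv.name] == "case_specific"]
        bg = [small_cohort.peak_sequence(iv) for iv in small_cohort.base_peaks
              if labels[iv.name] == "control_specific"]
        enr = motif_enrichment(fg, bg, pwm, alpha=1e-5)
        assert enr.fg_hit_fraction > enr.bg_hit_fraction

    def test_empty_sets_rejected(self, rng):
        pwm = _random_pwm(rng, 4)
        with pytest.raises(Exception):
            motif_enrichment([], ["ACGT"], pwm)


class TestPooledBackground:
    def test_composition_counts(self):
        bg = pooled_background(["AAAA", "CCCC"])
        assert bg[0] == pytest.approx(bg[1])
        assert bg[0] > bg[2]
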