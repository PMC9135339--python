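"""Pairwise case-vs-control differential peak analysis.

The engine is an M-A (log-ratio vs log-intensity) comparison of read counts
at matched peaks between one case and one control subject: peaks present in
both subjects ("common", matched by >= 1 bp overlap) anchor a robust linear
baseline M = a + b*A, peaks are rescaled to M_norm = M - (a + b*A), and a
two-sided Audic-Claverie Bayesian p-value on library-scaled counts gates
significance.  A peak is case-specific when 2^M_norm > fc_threshold and
p < p_threshold (symmetrically for control-specific), shared otherwise.
Peaks present in only one subject enter the same rule with a pseudocounted
zero on the absent side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConfigurationError, GenomicInterval, PeakSet, intersect

PSEUDOCOUNT = 0.5

SHARED = "shared"
CASE_SPECIFIC = "case_specific"
CONTROL_SPECIFIC = "control_specific"


@dataclass
class MAPoint:
    peak_id: str
    chrom: str
    start: int
    end: int
    x_case: float
    x_ctrl: float
    M: float = np.nan
    A: float = np.nan
    M_norm: float = np.nan
    p_value: float = np.nan
    origin: str = "common"          # common / case_unique / ctrl_unique
    subject_id: str = ""            # subject whose peak defines the record
    label: str = SHARED


@dataclass
class PairwiseDifferentialResult:
    pair_id: str
    points: list[MAPoint] = field(default_factory=list)
    a: float = 0.0                  # baseline intercept
    b: float = 0.0                  # baseline slope
    normalized: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"peak_id": p.peak_id, "chrom": p.chrom, "start": p.start,
              "end": p.end, "x_case": p.x_case, "x_ctrl": p.x_ctrl,
              "M": p.M, "A": p.A, "M_norm": p.M_norm, "p": p.p_value,
              "origin": p.origin, "label": p.label}
             for p in self.points])

    def label_counts(self) -> dict[str, int]:
        out = {SHARED: 0, CASE_SPECIFIC: 0, CONTROL_SPECIFIC: 0}
        for p in self.points:
            out[p.label] += 1
        return out


def match_peaks(case: PeakSet, ctrl: PeakSet
                ) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Partition peaks of a matched pair into common pairs and unique sets.

    Overlap chains are resolved greedily to the best-overlapping partner
    (largest shared bp; ties to the leftmost indices), so each peak appears
    in exactly one category.
    """
    if case.counts is None or ctrl.counts is None:
        raise ConfigurationError("both PeakSets must carry counts")
    candidates = []
    for i, j in intersect(case.intervals, ctrl.intervals):
        a, b = case.intervals[i], ctrl.intervals[j]
        ov = min(a.end, b.end) - max(a.start, b.start)
        candidates.append((-ov, i, j))
    candidates.sort()
    used_case: set[int] = set()
    used_ctrl: set[int] = set()
    common: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_case or j in used_ctrl:
            continue
        used_case.add(i)
        used_ctrl.add(j)
        common.append((i, j))
    common.sort()
    case_unique = [i for i in range(len(case)) if i not in used_case]
    ctrl_unique = [j for j in range(len(ctrl)) if j not in used_ctrl]
    return common, case_unique, ctrl_unique


def ma_values(x_case: np.ndarray, x_ctrl: np.ndarray,
              pseudocount: float = PSEUDOCOUNT) -> tuple[np.ndarray, np.ndarray]:
    """M = log2 case/control, A = half the log2 product, both pseudocounted."""
    xc = np.asarray(x_case, dtype=float) + pseudocount
    xt = np.asarray(x_ctrl, dtype=float) + pseudocount
    return np.log2(xc / xt), 0.5 * np.log2(xc * xt)


def ma_normalize(M: np.ndarray, A: np.ndarray,
                 robust: bool = True) -> tuple[float, float]:
    """Fit the baseline M = a + b*A on common peaks (Theil-Sen by default).

    Raises ConfigurationError below 10 common peaks; callers may then skip
    normalization and use raw M.
    """
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    if len(M) < 10:
        raise ConfigurationError(
            f"normalization needs >= 10 common peaks, got {len(M)}")
    if robust:
        if np.ptp(A) == 0:  # degenerate abscissa: flat baseline at the median
            return float(np.median(M)), 0.0
        slope, intercept, _, _ = stats.theilslopes(M, A)
    else:
        slope, intercept, *_ = stats.linregress(A, M)
    return float(intercept), float(slope)


def differential_pvalue(x_case, x_ctrl, lib_case: float, lib_ctrl: float):
    """Two-sided Audic-Claverie Bayesian p-value on library-scaled counts.

    Given the case count x with library size N1, the posterior-predictive
    distribution of the control count is negative binomial with size x+1 and
    success probability N1/(N1+N2); doubling the smaller tail at the observed
    control count gives a directional p.  Because that tail is not exchange-
    symmetric, the pinned statistic averages the two conditioning
    orientations, which makes p(x, y) = p(y, x) exact whenever the libraries
    are equal.
    """
    if lib_case <= 0 or lib_ctrl <= 0:
        raise ValueError("library sizes must be positive")
    x = np.atleast_1d(np.asarray(x_case, dtype=np.int64))
    y = np.atleast_1d(np.asarray(x_ctrl, dtype=np.int64))
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")

    def _two_sided(a, b, p_succ):
        dist = stats.nbinom(a + 1, p_succ)
        return np.minimum(1.0, 2.0 * np.minimum(dist.cdf(b), dist.sf(b - 1)))

    p1 = _two_sided(x, y, lib_case / (lib_case + lib_ctrl))
    p2 = _two_sided(y, x, lib_ctrl / (lib_case + lib_ctrl))
    p = np.minimum(1.0, 0.5 * (p1 + p2))
    return p if np.ndim(x_case) or np.ndim(x_ctrl) else float(p[0])


def classify(result: PairwiseDifferentialResult, fc_threshold: float = 1.5,
             p_threshold: float = 0.05) -> PairwiseDifferentialResult:
    """Label each peak shared / case_specific / control_specific in place."""
    log_fc = np.log2(fc_threshold)
    for pt in result.points:
        if pt.M_norm > log_fc and pt.p_value < p_threshold:
            pt.label = CASE_SPECIFIC
        elif -pt.M_norm > log_fc and pt.p_value < p_threshold:
            pt.label = CONTROL_SPECIFIC
        else:
            pt.label = SHARED
    return result


def pairwise_differential(case: PeakSet, ctrl: PeakSet, pair_id: str = "",
                          fc_threshold: float = 1.5, p_threshold: float = 0.05,
                          lib_case: float | None = None,
                          lib_ctrl: float | None = None,
                          robust: bool = True) -> PairwiseDifferentialResult:
    """Full pairwise analysis: match, normalize, test, classify.

    Library sizes default to each subject's total counts.  Swapping the two
    inputs swaps case/control labels exactly.
    """
    common, case_uni, ctrl_uni = match_peaks(case, ctrl)
    lib_case = float(np.sum(case.counts)) if lib_case is None else lib_case
    lib_ctrl = float(np.sum(ctrl.counts)) if lib_ctrl is None else lib_ctrl

    points: list[MAPoint] = []
    for i, j in common:
        iv = case.intervals[i]
        points.append(MAPoint(iv.name or f"case_{i}", iv.chrom,
                              min(iv.start, ctrl.intervals[j].start),
                              max(iv.end, ctrl.intervals[j].end),
                              float(case.counts[i]), float(ctrl.counts[j]),
                              origin="common", subject_id=case.subject_id))
    for i in case_uni:
        iv = case.intervals[i]
        points.append(MAPoint(iv.name or f"case_{i}", iv.chrom, iv.start,
                              iv.end, float(case.counts[i]), 0.0,
                              origin="case_unique", subject_id=case.subject_id))
    for j in ctrl_uni:
        iv = ctrl.intervals[j]
        points.append(MAPoint(iv.name or f"ctrl_{j}", iv.chrom, iv.start,
                              iv.end, 0.0, float(ctrl.counts[j]),
                              origin="ctrl_unique", subject_id=ctrl.subject_id))

    xc = np.array([p.x_case for p in points])
    xt = np.array([p.x_ctrl for p in points])
    M, A = ma_values(xc, xt)
    is_common = np.array([p.origin == "common" for p in points])

    result = PairwiseDifferentialResult(pair_id, points)
    try:
        a, b = ma_normalize(M[is_common], A[is_common], robust=robust)
        result.a, result.b, result.normalized = a, b, True
        M_norm = M - (a + b * A)
    except ConfigurationError:
        M_norm = M  # too few common peaks: raw M, flagged un-normalized
    pvals = differential_pvalue(xc.astype(np.int64), xt.astype(np.int64),
                                lib_case, lib_ctrl)
    for pt, m, av, mn, p in zip(points, M, A, M_norm, pvals):
        pt.M, pt.A, pt.M_norm, pt.p_value = float(m), float(av), float(mn), float(p)
    return classify(result, fc_threshold, p_threshold)


def frip(read_intervals: list[GenomicInterval], peaks: PeakSet) -> float:
    """Fraction of reads overlapping any peak (FRiP QC statistic)."""
    if not read_intervals:
        raise ValueError("FRiP undefined for zero reads")
    if len(peaks) == 0:
        return 0.0
    hit = {i for i, _ in intersect(read_intervals, peaks.intervals)}
    return len(hit) / len(read_intervals)
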