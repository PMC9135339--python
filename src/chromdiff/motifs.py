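"""PWM scanning and case-vs-control motif enrichment contrasts.

A peak "contains" a motif when at least one position on either strand scores
at or above a cutoff chosen so that the per-position hit probability under a
background base composition is <= alpha (default 1e-4).  The cutoff comes
from the exact score distribution, computed by dynamic programming over the
per-position score values (exact state merging up to ~2.6e5 states, which
covers all widths <= 9 exactly; wider matrices fall back to a fine grid).
Enrichment between two peak sets is the one-sided Fisher exact test on the
2x2 peak-contains-hit table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .core import ConfigurationError, GenomicInterval

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_MAX_EXACT_STATES = 1 << 18


@dataclass
class PWM:
    """Position probability matrix (width x 4 over A,C,G,T) with background."""

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def with_background(self, background: np.ndarray) -> "PWM":
        return PWM(self.motif_id, self.matrix, np.asarray(background, float))


def pwm_from_counts(motif_id: str, counts: np.ndarray,
                    pseudocount: float = 1e-3,
                    background: np.ndarray | None = None) -> PWM:
    counts = np.asarray(counts, dtype=float)
    if np.any(counts.sum(axis=1) <= 0):
        raise ValueError("each PWM row must have a positive sum")
    probs = (counts + pseudocount) / (counts + pseudocount).sum(axis=1,
                                                                keepdims=True)
    bg = np.full(4, 0.25) if background is None else background
    return PWM(motif_id, probs, bg)


def read_pwm(path: str | Path, motif_id: str | None = None,
             pseudocount: float = 1e-3) -> PWM:
    """Read a Cis-BP-style (rows = positions) or JASPAR-style (rows = bases)
    PFM text file; counts or frequencies are normalized to probabilities."""
    path = Path(path)
    rows: list[list[float]] = []
    jaspar: dict[str, list[float]] = {}
    header_id = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                header_id = line[1:].split()[0]
                continue
            fields = line.replace("[", " ").replace("]", " ").split()
            if fields[0].upper() in _BASE_INDEX and not _is_number(fields[0]):
                base = fields[0].upper()
                jaspar[base] = [float(x) for x in fields[1:]
                                if _is_number(x)]
                continue
            if fields[0].lower() in ("pos", "position"):
                continue  # Cis-BP header row
            numeric = [float(x) for x in fields if _is_number(x)]
            if len(numeric) == 5:
                numeric = numeric[1:]  # leading position column
            if len(numeric) != 4:
                raise ValueError(f"{path}: row does not parse as 4 numerics: {line!r}")
            rows.append(numeric)
    if jaspar:
        if set(jaspar) != set("ACGT"):
            raise ValueError(f"{path}: JASPAR block must cover A,C,G,T")
        counts = np.array([jaspar[b] for b in "ACGT"]).T
    else:
        counts = np.array(rows)
    return pwm_from_counts(motif_id or header_id or path.stem, counts,
                           pseudocount)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def encode_sequence(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def score_positions(pwm: PWM, sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-position log-odds scores on (+, -) strands.

    The minus-strand score at position i is the score of the reverse
    complement of the window starting at i.  Windows containing non-ACGT
    characters score -inf.  Sequences shorter than the motif give empty
    arrays.
    """
    w = pwm.width
    enc = encode_sequence(sequence)
    n = len(enc) - w + 1
    if n <= 0:
        return np.empty(0), np.empty(0)
    lo = pwm.log_odds()
    lo_rc = lo[::-1, ::-1]  # scanning with the revcomp matrix == scoring revcomp
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows < 0, 0, windows)
    pos_idx = np.arange(w)
    plus = lo[pos_idx, safe].sum(axis=1)
    minus = lo_rc[pos_idx, safe].sum(axis=1)
    plus[~valid] = -np.inf
    minus[~valid] = -np.inf
    return plus, minus


def score_distribution(pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Exact (score, probability) pairs of the log-odds score under the
    background, by DP over positions with state merging."""
    lo = pwm.log_odds()
    bg = pwm.background
    scores = np.array([0.0])
    probs = np.array([1.0])
    for j in range(pwm.width):
        scores = (scores[:, None] + lo[j][None, :]).ravel()
        probs = (probs[:, None] * bg[None, :]).ravel()
        order = np.argsort(scores, kind="stable")
        scores, probs = scores[order], probs[order]
        # merge numerically identical states
        keep = np.concatenate([[True], np.diff(scores) > 1e-12])
        group = np.cumsum(keep) - 1
        merged_p = np.zeros(group[-1] + 1)
        np.add.at(merged_p, group, probs)
        scores, probs = scores[keep], merged_p
        if len(scores) > _MAX_EXACT_STATES:
            # fall back to a fine grid for very wide matrices
            grid = np.round(scores / 1e-4).astype(np.int64)
            uniq, inv = np.unique(grid, return_inverse=True)
            merged_p = np.zeros(len(uniq))
            np.add.at(merged_p, inv, probs)
            scores, probs = uniq * 1e-4, merged_p
    return scores, probs


def hit_threshold(pwm: PWM, alpha: float = 1e-4) -> float:
    """Smallest achievable score t with P(score >= t | background) <= alpha.

    If even the maximal score exceeds alpha in tail mass, a cutoff just above
    the maximum is returned (no sequence can be a hit).
    """
    if not (0 < alpha < 0.5):
        raise ValueError("alpha must be in (0, 0.5)")
    scores, probs = score_distribution(pwm)
    tail = np.cumsum(probs[::-1])[::-1]  # tail[i] = P(score >= scores[i])
    ok = tail <= alpha
    if not ok.any():
        return float(scores[-1]) + 1.0
    return float(scores[np.argmax(ok)])


def peak_contains_hit(pwm: PWM, sequence: str, cutoff: float) -> bool:
    plus, minus = score_positions(pwm, sequence)
    if len(plus) == 0:
        return False
    return bool((plus >= cutoff).any() or (minus >= cutoff).any())


@dataclass
class MotifEnrichment:
    motif_id: str
    fg_hit_fraction: float
    bg_hit_fraction: float
    p_value: float
    odds_ratio: float
    fg_n: int
    bg_n: int
    fg_hits: int
    bg_hits: int
    cutoff: float


def pooled_background(sequences: list[str]) -> np.ndarray:
    """Base composition of the pooled sequences (pseudocounted)."""
    counts = np.ones(4)
    for seq in sequences:
        enc = encode_sequence(seq)
        counts += np.bincount(enc[enc >= 0], minlength=4)
    return counts / counts.sum()


def motif_enrichment(fg_sequences: list[str], bg_sequences: list[str],
                     pwm: PWM, alpha: float = 1e-4,
                     pool_background: bool = True) -> MotifEnrichment:
    """One-sided Fisher exact enrichment of motif-containing peaks, fg > bg."""
    if not fg_sequences or not bg_sequences:
        raise ConfigurationError("foreground and background must be non-empty")
    if pool_background:
        pwm = pwm.with_background(pooled_background(fg_sequences + bg_sequences))
    cutoff = hit_threshold(pwm, alpha)
    fg_hits = sum(peak_contains_hit(pwm, s, cutoff) for s in fg_sequences)
    bg_hits = sum(peak_contains_hit(pwm, s, cutoff) for s in bg_sequences)
    table = [[fg_hits, len(fg_sequences) - fg_hits],
             [bg_hits, len(bg_sequences) - bg_hits]]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return MotifEnrichment(pwm.motif_id, fg_hits / len(fg_sequences),
                           bg_hits / len(bg_sequences), float(p), float(odds),
                           len(fg_sequences), len(bg_sequences),
                           int(fg_hits), int(bg_hits), cutoff)


def extract_sequences(genome_fasta, intervals: list[GenomicInterval]) -> list[str]:
    """Peak-span sequences from an indexed FASTA (pyfaidx Fasta or dict of str)."""
    out = []
    for iv in intervals:
        record = genome_fasta[iv.chrom]
        out.append(str(record[iv.start:iv.end]))
    return out
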