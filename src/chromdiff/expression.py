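"""Expression fold-change filtering, consistency, and peak-window integration.

Expression is FPKM-normalized; pairwise differential calls use a bare
fold-change gate (strictly greater than 1.5 by default, no significance
test), aggregated across matched pairs by the same at-least-three-pairs rule
used for peaks.  Genes are linked to peak sets through a window around the
TSS (default +/- 100 kb); a generic hypergeometric over-representation test
covers annotation gene sets.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ConfigurationError, GeneModel, GenomicInterval

UP = "up"
DOWN = "down"
NONE = "none"


def fpkm(counts, gene_length_bp, library_size):
    """Fragments per kilobase per million: count * 1e9 / (length * library)."""
    counts = np.asarray(counts, dtype=float)
    length = np.asarray(gene_length_bp, dtype=float)
    lib = np.asarray(library_size, dtype=float)
    if np.any(length <= 0) or np.any(lib <= 0):
        raise ValueError("gene length and library size must be positive")
    return counts * 1e9 / (length * lib)


def read_gene_table(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    return [GeneModel(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand),
                      int(r.length_bp))
            for r in df.itertuples(index=False)]


def fpkm_table(counts: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Per-subject FPKM from a genes x subjects count matrix.

    Library sizes are each subject's total mapped count.
    """
    lengths = pd.Series({g.gene_id: g.length_bp for g in genes})
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ConfigurationError("count matrix contains genes absent from the table")
    lib = counts.sum(axis=0)
    return counts.mul(1e9).div(lengths, axis=0).div(lib, axis=1)


def pairwise_de(case_fpkm, ctrl_fpkm, fc: float = 1.5,
                pseudo: float = 0.1):
    """Per-gene direction: up iff (case+pseudo)/(ctrl+pseudo) > fc, strictly;
    down for the reciprocal; none otherwise."""
    case = np.asarray(case_fpkm, dtype=float) + pseudo
    ctrl = np.asarray(ctrl_fpkm, dtype=float) + pseudo
    ratio = case / ctrl
    calls = np.where(ratio > fc, UP, np.where(1.0 / ratio > fc, DOWN, NONE))
    return calls if calls.ndim else str(calls)


def consistent_genes(calls: pd.DataFrame, min_pairs: int = 3
                     ) -> tuple[set[str], set[str]]:
    """Genes called up (down) in >= min_pairs of the genes x pairs call matrix."""
    if calls.shape[1] < min_pairs:
        raise ConfigurationError(
            f"min_pairs={min_pairs} exceeds the {calls.shape[1]} pairs available")
    up = set(calls.index[(calls == UP).sum(axis=1) >= min_pairs])
    down = set(calls.index[(calls == DOWN).sum(axis=1) >= min_pairs])
    return up, down


def window_overlap(genes: list[GeneModel], peaks: list[GenomicInterval],
                   window_bp: int = 100_000, anchor: str = "tss"
                   ) -> tuple[float, dict[str, bool]]:
    """Fraction of genes with >= 1 peak in [anchor - window, anchor + window).

    anchor="tss" (default) centers the window on the TSS; anchor="body"
    extends it around the TSS-to-TSS+length span.
    """
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for iv in peaks:
        starts.setdefault(iv.chrom, []).append(iv.start)
        ends.setdefault(iv.chrom, []).append(iv.end)
    for chrom in starts:
        order = np.argsort(starts[chrom])
        starts[chrom] = np.asarray(starts[chrom])[order]
        ends[chrom] = np.asarray(ends[chrom])[order]
    flags: dict[str, bool] = {}
    for g in genes:
        if anchor == "tss":
            lo, hi = g.tss - window_bp, g.tss + window_bp
        elif anchor == "body":
            body_lo = min(g.tss, g.tss + (g.length_bp if g.strand == "+" else -g.length_bp))
            body_hi = max(g.tss, g.tss + (g.length_bp if g.strand == "+" else -g.length_bp))
            lo, hi = body_lo - window_bp, body_hi + window_bp
        else:
            raise ValueError("anchor must be 'tss' or 'body'")
        lo = max(0, lo)
        s = starts.get(g.chrom)
        if s is None:
            flags[g.gene_id] = False
            continue
        # any peak with start < hi and end > lo
        k = np.searchsorted(s, hi, side="left")
        flags[g.gene_id] = bool((ends[g.chrom][:k] > lo).any())
    frac = sum(flags.values()) / len(flags) if flags else 0.0
    return frac, flags


def gene_set_enrichment(query: set[str], annotation_sets: dict[str, set[str]],
                        universe: set[str]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per set, BH-corrected."""
    if not universe:
        raise ConfigurationError("universe is empty")
    if not set(query) <= set(universe):
        raise ConfigurationError("query genes must be a subset of the universe")
    rows = []
    for set_id, members in annotation_sets.items():
        members = set(members) & set(universe)
        k = len(query & members)
        # P(X >= k) with X ~ Hypergeom(N=|universe|, K=|set|, n=|query|)
        p = stats.hypergeom.sf(k - 1, len(universe), len(members), len(query))
        rows.append({"set_id": set_id, "set_size": len(members),
                     "overlap": k, "p": float(min(1.0, p))})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3:
                sets[fields[0]] = set(fields[2:])
    return sets
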