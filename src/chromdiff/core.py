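"""Domain types, interval algebra, and readers/writers for genomic formats.

All coordinates are 0-based half-open (BED convention).  VCF positions are
converted by -1 on read so that a single convention holds package-wide.
Overlap everywhere means >= 1 shared base pair; touching half-open intervals
([0,10) and [10,20)) do not overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"


class BedParseError(ValueError):
    """A BED line could not be parsed; message names the line number."""


class ConfigurationError(ValueError):
    """Inputs are inconsistent with the requested operation."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        # ties broken by (end, name) for determinism
        return (self.chrom, self.start, self.end, self.name or "")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=GenomicInterval.sort_key)


@dataclass
class PeakSet:
    """Peaks for one subject/assay/condition, with optional per-peak read counts."""

    subject_id: str
    assay: str  # "ATAC" or "CHIP"
    condition: str  # "case" or "control"
    intervals: list[GenomicInterval] = field(default_factory=list)
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.assay not in ("ATAC", "CHIP"):
            raise ValueError(f"assay must be ATAC or CHIP, got {self.assay!r}")
        if self.condition not in ("case", "control"):
            raise ValueError(f"condition must be case or control, got {self.condition!r}")
        self.intervals = sort_intervals(self.intervals)
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if len(self.counts) != len(self.intervals):
                raise ValueError(
                    f"counts ({len(self.counts)}) do not align with intervals "
                    f"({len(self.intervals)})"
                )
            if np.any(self.counts < 0):
                raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.intervals)

    def with_counts(self, counts: np.ndarray) -> "PeakSet":
        return PeakSet(self.subject_id, self.assay, self.condition,
                       list(self.intervals), np.asarray(counts))


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV with per-subject genotype calls (0-based position)."""

    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_allele: str
    genotypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.id}: ref and alt alleles are identical")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"{self.id}: only single-nucleotide variants supported")

    def as_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + 1, name=self.id)


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored at its TSS, with exonic length for FPKM normalization."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.gene_id}: length_bp must be positive")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED5 into a sorted interval list (half-open, 0-based)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            try:
                intervals.append(GenomicInterval(fields[0], start, end, name, score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return sort_intervals(intervals)


def read_bed(path: str | Path, subject_id: str = "", assay: str = "ATAC",
             condition: str = "case") -> PeakSet:
    """Read a BED file into a PeakSet (no counts attached)."""
    return PeakSet(subject_id, assay, condition, read_bed_intervals(path))


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    """Write sorted BED; emits name/score columns when any interval has them."""
    ivs = sort_intervals(intervals)
    any_name = any(iv.name is not None for iv in ivs)
    any_score = any(iv.score is not None for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if any_name or any_score:
                cols.append(iv.name if iv.name is not None else ".")
            if any_score:
                cols.append(f"{iv.score:g}" if iv.score is not None else ".")
            fh.write("\t".join(cols) + "\n")


def read_counts_tsv(path: str | Path) -> dict[str, int]:
    """Read a two-column peak_id<TAB>count table."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("peak_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            counts[fields[0]] = int(fields[1])
    return counts


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def _trees_by_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    return trees

def intersect(a: Sequence[GenomicInterval],
              b: Sequence[GenomicInterval]) -> list[tuple[int, int]]:
    """All index pairs (i, j) where a[i] and b[j] share >= 1 bp.

    Result is sorted by (i, j); half-open semantics.
    """
    trees = _trees_by_chrom(b)
    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            pairs.append((i, hit.data))
    pairs.sort()
    return pairs


def merge_union(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal disjoint interval set covering exactly the input union."""
    merged: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = replace(merged[-1], end=iv.end, name=None, score=None)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def total_bp(intervals: Sequence[GenomicInterval]) -> int:
    return sum(iv.length for iv in merge_union(intervals))


def filter_blacklist(peaks: PeakSet,
                     blacklist: Sequence[GenomicInterval]) -> PeakSet:
    """Drop peaks overlapping any blacklist interval; counts stay aligned."""
    hit_idx = {i for i, _ in intersect(peaks.intervals, list(blacklist))}
    keep = [i for i in range(len(peaks)) if i not in hit_idx]
    counts = peaks.counts[keep] if peaks.counts is not None else None
    return PeakSet(peaks.subject_id, peaks.assay, peaks.condition,
                   [peaks.intervals[i] for i in keep], counts)


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def read_vcf_genotypes(path: str | Path,
                       subject_ids: Sequence[str]) -> list[VariantRecord]:
    """Read biallelic SNV genotypes for the named subjects from a VCF.

    Multiallelic records and indels are skipped (count logged).  Positions
    are converted to 0-based.  Raises ConfigurationError if a requested
    subject is absent from the VCF header.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_index = {s: k for k, s in enumerate(vcf.samples)}
    missing = [s for s in subject_ids if s not in sample_index]
    if missing:
        raise ConfigurationError(f"subjects absent from VCF: {missing}")

    records: list[VariantRecord] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        genotypes: dict[str, str] = {}
        for s in subject_ids:
            gt = var.genotypes[sample_index[s]]
            alleles = [a for a in gt[:-1]]
            if any(a < 0 for a in alleles):
                genotypes[s] = MISSING
            elif all(a == 0 for a in alleles):
                genotypes[s] = HOM_REF
            elif all(a == 1 for a in alleles):
                genotypes[s] = HOM_ALT
            else:
                genotypes[s] = HET
        records.append(VariantRecord(var.CHROM, var.POS - 1,
                                     var.ID or f"{var.CHROM}:{var.POS}",
                                     var.REF, var.ALT[0], genotypes))
    if n_skipped:
        logger.info("read_vcf_genotypes: skipped %d multiallelic/indel records",
                    n_skipped)
    return records
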