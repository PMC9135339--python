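"""Allele-dependent accessibility calling at heterozygous variants in peaks.

For each subject, candidate variants are those heterozygous in that subject
and located inside one of that subject's peaks.  At each candidate the reads
supporting each allele are compared: the strong-allele fraction p_hat gives
an imbalance statistic m = 2*|p_hat - 0.5| and an exact two-sided binomial
test against 0.5.  A reproducibility score combining read depth and
imbalance, ars = m * min(1, log10(n+1)/2) (depth component saturating at 100
reads), is thresholded at 0.4 (inclusive) to call a measurement allelic.
The score is deliberately isolated in one function so an alternative
formulation can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import HET, ConfigurationError, PeakSet, VariantRecord

ARS_THRESHOLD = 0.4

NOT_CANDIDATE = "not_candidate"     # not het, or not inside a peak
HET_NOT_ALLELIC = "het_not_allelic"
ALLELIC = "allelic"


@dataclass
class AllelicCountRecord:
    variant_id: str
    subject_id: str
    assay: str
    n_ref: int
    n_alt: int
    strong_allele: str = ""
    p_hat: float = np.nan
    m: float = np.nan
    binomial_p: float = np.nan
    ars: float = np.nan
    is_allelic: bool = False

    @property
    def n_total(self) -> int:
        return self.n_ref + self.n_alt


def read_allelic_counts(path: str | Path) -> list[AllelicCountRecord]:
    """Read a tabulated pileup TSV: variant_id, subject_id, assay, n_ref, n_alt."""
    df = pd.read_csv(path, sep="\t")
    return [AllelicCountRecord(str(r.variant_id), str(r.subject_id),
                               str(r.assay), int(r.n_ref), int(r.n_alt))
            for r in df.itertuples(index=False)]


def candidate_variants(variants: list[VariantRecord], peaks: PeakSet,
                       subject: str) -> list[VariantRecord]:
    """Variants heterozygous in `subject` and inside >= 1 of its peaks."""
    from .core import intersect

    missing = [v.id for v in variants if subject not in v.genotypes]
    if missing:
        raise ConfigurationError(
            f"subject {subject!r} absent from genotypes of {len(missing)} variants")
    het_vars = [v for v in variants if v.genotypes[subject] == HET]
    var_ivs = [v.as_interval() for v in het_vars]
    in_peak = {i for i, _ in intersect(var_ivs, peaks.intervals)}
    return [v for i, v in enumerate(het_vars) if i in in_peak]


def imbalance(n_ref: int, n_alt: int) -> tuple[str, float, float, float]:
    """(strong_allele, p_hat, m, binomial_p) at one heterozygote.

    p_hat is the strong-allele read fraction (ties broken toward ref, which
    m = 0 makes inert); the test is the exact two-sided binomial vs 0.5.
    """
    n = n_ref + n_alt
    if n < 1:
        raise ValueError("imbalance undefined for zero total reads")
    strong = "ref" if n_ref >= n_alt else "alt"
    p_hat = max(n_ref, n_alt) / n
    m = 2.0 * abs(p_hat - 0.5)
    p = stats.binomtest(n_ref, n, 0.5, alternative="two-sided").pvalue
    return strong, p_hat, m, float(min(1.0, p))


def ars_score(n_total: int, m: float) -> float:
    """Reproducibility score in [0,1]: imbalance times a saturating depth term.

    ars = m * min(1, log10(n_total + 1) / 2); the depth component reaches 1
    at ~100 reads.  Monotone non-decreasing in both arguments.
    """
    if n_total < 1:
        raise ValueError("ars undefined for zero reads")
    if not (0.0 <= m <= 1.0):
        raise ValueError("m must be in [0, 1]")
    depth = min(1.0, np.log10(n_total + 1) / 2.0)
    return float(m * depth)


def score_records(records: list[AllelicCountRecord]) -> list[AllelicCountRecord]:
    """Fill imbalance statistics and ARS for every record with >= 1 read."""
    for rec in records:
        if rec.n_total < 1:
            continue
        rec.strong_allele, rec.p_hat, rec.m, rec.binomial_p = imbalance(
            rec.n_ref, rec.n_alt)
        rec.ars = ars_score(rec.n_total, rec.m)
    return records


def call_allelic(records: list[AllelicCountRecord],
                 ars_threshold: float = ARS_THRESHOLD
                 ) -> list[AllelicCountRecord]:
    """Flag records with ars >= threshold (inclusive) as allelic."""
    for rec in records:
        rec.is_allelic = bool(not np.isnan(rec.ars) and rec.ars >= ars_threshold)
    return records


def aggregate_variants(records: list[AllelicCountRecord],
                       subjects: list[str] | None = None) -> pd.DataFrame:
    """Variant x subject matrix of {allelic, het_not_allelic, not_candidate}.

    Also usable to count discovery "opportunities": cells that are candidates
    (het and inside a peak, i.e. present in the record list) regardless of
    the allelic call.
    """
    if subjects is None:
        subjects = sorted({r.subject_id for r in records})
    variants = sorted({r.variant_id for r in records})
    matrix = pd.DataFrame(NOT_CANDIDATE, index=variants, columns=subjects)
    for rec in records:
        matrix.loc[rec.variant_id, rec.subject_id] = (
            ALLELIC if rec.is_allelic else HET_NOT_ALLELIC)
    return matrix


def summarize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-variant counts of allelic calls and opportunities."""
    return pd.DataFrame({
        "n_allelic_subjects": (matrix == ALLELIC).sum(axis=1),
        "n_opportunities": (matrix != NOT_CANDIDATE).sum(axis=1),
    })


def pooled_imbalance(records: list[AllelicCountRecord]
                     ) -> tuple[int, int, float]:
    """Reads pooled across subjects at one variant: (n_ref, n_alt, p_hat)."""
    n_ref = sum(r.n_ref for r in records)
    n_alt = sum(r.n_alt for r in records)
    _, p_hat, _, _ = imbalance(n_ref, n_alt)
    return n_ref, n_alt, p_hat
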