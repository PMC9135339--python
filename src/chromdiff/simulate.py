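"""Synthetic matched case/control cohort generator with recorded ground truth.

Emulates the data structure of a six-pair ATAC/ChIP/RNA cohort study: a small
multi-chromosome genome, per-subject peak landscapes with shared and
condition-specific peaks (negative-binomial read counts with a multiplicative
fold effect on the specific peaks), transcription-factor motif instances
planted preferentially into case-specific peaks, heterozygous SNVs inside
peaks with allele-biased read sampling, and a gene-expression channel with
planted consistently up/down genes whose TSSs sit near condition-specific
peaks.

Everything is driven by one integer seed; identical seeds give byte-identical
serialized bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import (
    HET, HOM_ALT, HOM_REF,
    GeneModel, GenomicInterval, PeakSet, VariantRecord, write_bed,
)

BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

# A p50-class dimer-like motif (GGGRATTYCC consensus): informative flanks,
# degenerate core. Used as the default planted motif.
DEFAULT_MOTIF_COUNTS = np.array([
    # A    C    G    T
    [ 2,   2,  92,   4],
    [ 1,   1,  97,   1],
    [ 1,   1,  97,   1],
    [40,   5,  50,   5],
    [55,  15,  15,  15],
    [25,  25,  25,  25],
    [15,  15,  15,  55],
    [ 5,  45,   5,  45],
    [ 1,  97,   1,   1],
    [ 4,  92,   2,   2],
], dtype=float)


class GenerationError(RuntimeError):
    """The requested cohort cannot be realized on the genome model."""


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the matched-pair study design this simulator emulates:
    six case/control pairs, ~90% of peaks shared within a pair, a 3-fold
    accessibility effect on condition-specific peaks, motif instances planted
    in 30% of case-specific peaks vs 1% elsewhere, and allele-biased read
    sampling at 85% in imbalanced heterozygotes.
    """

    n_pairs: int = 6
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000,
                                 "chr3": 1_000_000})
    n_shared_peaks: int = 2000
    n_case_specific: int = 100
    n_control_specific: int = 100
    peak_width: int = 500
    peak_gap: int = 200
    boundary_jitter: int = 20
    mean_count: float = 50.0
    case_fold_change: float = 3.0
    count_dispersion: float = 0.005
    motif_plant_rate_fg: float = 0.3
    motif_plant_rate_bg: float = 0.01
    n_het_variants_in_peaks: int = 200
    variant_case_peak_bias: float = 0.3
    imbalanced_fraction: float = 0.5
    allelic_bias: float = 0.85
    mean_depth_at_variant: float = 30.0
    het_probability: float = 0.6
    n_genes: int = 300
    n_up_genes: int = 20
    n_down_genes: int = 20
    expression_fold: float = 2.5
    expression_mean_count: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 <= self.allelic_bias <= 1.0):
            raise ValueError("allelic_bias must be in [0.5, 1]")
        for name in ("n_pairs", "n_shared_peaks", "n_case_specific",
                     "n_control_specific", "n_het_variants_in_peaks",
                     "n_genes", "n_up_genes", "n_down_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GroundTruth:
    """Truth channel: what was planted where."""

    peak_labels: dict[str, str]            # peak name -> shared/case_specific/control_specific
    motif_planted: dict[str, bool]         # peak name -> planted flag
    planted_positions: dict[str, tuple[int, str]]  # peak name -> (genome pos, strand)
    variant_imbalance: dict[str, tuple[bool, str]]  # variant id -> (imbalanced, favored allele)
    up_genes: list[str]
    down_genes: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)


@dataclass
class CohortBundle:
    """Everything a downstream stage needs, plus the truth."""

    config: CohortConfig
    genome: dict[str, np.ndarray]          # chrom -> uint8 base-index array
    base_peaks: list[GenomicInterval]      # the underlying peak landscape
    peaksets: dict[str, PeakSet]           # subject id -> jittered peaks with counts
    pairs: list[tuple[str, str]]           # (case subject, control subject)
    variants: list[VariantRecord]
    allelic_counts: list[dict]             # rows: variant_id, subject_id, assay, n_ref, n_alt
    genes: list[GeneModel]
    expression_counts: dict[str, np.ndarray]  # subject -> per-gene counts
    truth: GroundTruth

    def genome_fasta(self) -> str:
        out = []
        for chrom, arr in self.genome.items():
            out.append(f">{chrom}")
            seq = "".join(BASES[arr])
            out.extend(seq[i:i + 80] for i in range(0, len(seq), 80))
        return "\n".join(out) + "\n"

    def peak_sequence(self, iv: GenomicInterval) -> str:
        return "".join(BASES[self.genome[iv.chrom][iv.start:iv.end]])


def _negbin(rng: np.random.Generator, mean: np.ndarray,
            dispersion: float) -> np.ndarray:
    """NB with var = mean + dispersion * mean^2 (Poisson when dispersion=0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def sample_allelic_reads(depth: int, bias: float, rng: np.random.Generator,
                         favored: str = "alt") -> tuple[int, int]:
    """Sample (n_ref, n_alt) at a heterozygote: favored allele ~ Binomial(depth, bias)."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not (0.5 <= bias <= 1.0):
        raise ValueError("bias must be in [0.5, 1]")
    if depth == 0:
        return (0, 0)
    n_fav = int(rng.binomial(depth, bias))
    if favored == "ref":
        return (n_fav, depth - n_fav)
    return (depth - n_fav, n_fav)


def pwm_probabilities(counts: np.ndarray, pseudocount: float = 1e-3) -> np.ndarray:
    counts = np.asarray(counts, dtype=float) + pseudocount
    return counts / counts.sum(axis=1, keepdims=True)


def plant_motifs(genome: dict[str, np.ndarray], peaks: list[GenomicInterval],
                 plant_flags: np.ndarray, pwm_probs: np.ndarray,
                 rng: np.random.Generator, margin: int = 30,
                 plant_alpha: float = 1e-5) -> dict[str, tuple[int, str]]:
    """Overwrite one PWM-sampled instance into each flagged peak.

    Instances are sampled base-by-base from the PWM, resampling (up to 50
    tries, then the consensus) until the instance's own log-odds score clears
    the PWM's hit threshold at `plant_alpha`, so peak-level "contains >= 1
    hit" truth is unambiguous for any scanning alpha >= plant_alpha.  The
    instance lands at a uniform offset (keeping `margin` bp clear of both
    peak edges so per-subject boundary jitter cannot truncate it) on a
    uniform strand.  Returns peak name -> (genome start of instance, strand).
    """
    from .motifs import PWM, hit_threshold

    width = pwm_probs.shape[0]
    pwm = PWM("planted", pwm_probs, np.full(4, 0.25))
    cutoff = hit_threshold(pwm, plant_alpha)
    log_odds = pwm.log_odds()
    pos_idx = np.arange(width)
    planted: dict[str, tuple[int, str]] = {}
    for iv, flag in zip(peaks, plant_flags):
        if not flag:
            continue
        usable = iv.length - 2 * margin - width
        if usable < 0:
            raise GenerationError(f"motif (w={width}) longer than usable peak {iv.name}")
        offset = iv.start + margin + int(rng.integers(usable + 1))
        instance = None
        for _ in range(50):
            draw = np.array([rng.choice(4, p=row) for row in pwm_probs],
                            dtype=np.uint8)
            if log_odds[pos_idx, draw].sum() >= cutoff:
                instance = draw
                break
        if instance is None:
            instance = pwm_probs.argmax(axis=1).astype(np.uint8)
        strand = "+" if rng.integers(2) == 0 else "-"
        if strand == "-":
            instance = (3 - instance)[::-1]  # reverse complement in index space
        genome[iv.chrom][offset:offset + width] = instance
        planted[iv.name] = (offset, strand)
    return planted


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a full cohort bundle under the given study conditions."""
    root = np.random.SeedSequence(config.seed)
    (ss_genome, ss_peaks, ss_counts, ss_motifs, ss_variants,
     ss_expr) = root.spawn(6)

    rng_genome = np.random.default_rng(ss_genome)
    genome = {chrom: rng_genome.integers(0, 4, size=length, dtype=np.uint8)
              for chrom, length in config.chrom_lengths.items()}

    # --- peak landscape: non-overlapping slots on a fixed grid ---------------
    rng_peaks = np.random.default_rng(ss_peaks)
    step = config.peak_width + config.peak_gap
    slots: list[tuple[str, int]] = []
    for chrom, length in config.chrom_lengths.items():
        n_slots = (length - config.peak_gap) // step
        slots.extend((chrom, config.peak_gap + k * step) for k in range(n_slots))
    n_total = (config.n_shared_peaks + config.n_case_specific
               + config.n_control_specific)
    if n_total > len(slots):
        raise GenerationError(
            f"{n_total} peaks requested but genome model holds {len(slots)} slots")
    chosen = rng_peaks.choice(len(slots), size=n_total, replace=False)
    chosen.sort()
    labels = (["shared"] * config.n_shared_peaks
              + ["case_specific"] * config.n_case_specific
              + ["control_specific"] * config.n_control_specific)
    rng_peaks.shuffle(labels)
    base_peaks = []
    peak_labels: dict[str, str] = {}
    for k, slot_idx in enumerate(chosen):
        chrom, start = slots[slot_idx]
        name = f"pk{k:05d}"
        base_peaks.append(GenomicInterval(chrom, start, start + config.peak_width,
                                          name=name))
        peak_labels[name] = labels[k]
    label_arr = np.array([peak_labels[iv.name] for iv in base_peaks])

    # --- motif planting (case-specific peaks are foreground) ----------------
    rng_motifs = np.random.default_rng(ss_motifs)
    pwm_probs = pwm_probabilities(DEFAULT_MOTIF_COUNTS)
    rate = np.where(label_arr == "case_specific",
                    config.motif_plant_rate_fg, config.motif_plant_rate_bg)
    plant_flags = rng_motifs.random(n_total) < rate
    planted_positions = plant_motifs(genome, base_peaks, plant_flags,
                                     pwm_probs, rng_motifs,
                                     margin=config.boundary_jitter + 10)
    motif_planted = {iv.name: bool(f) for iv, f in zip(base_peaks, plant_flags)}

    # --- per-subject peaks and counts ---------------------------------------
    rng_counts = np.random.default_rng(ss_counts)
    base_mean = rng_counts.gamma(shape=4.0, scale=config.mean_count / 4.0,
                                 size=n_total) + 2.0
    pairs = [(f"AD{p+1}", f"CTL{p+1}") for p in range(config.n_pairs)]
    peaksets: dict[str, PeakSet] = {}
    for case_id, ctrl_id in pairs:
        for subject, cond in ((case_id, "case"), (ctrl_id, "control")):
            mean = base_mean.copy()
            if cond == "case":
                mean[label_arr == "case_specific"] *= config.case_fold_change
            else:
                mean[label_arr == "control_specific"] *= config.case_fold_change
            counts = _negbin(rng_counts, mean, config.count_dispersion)
            jit = rng_counts.integers(-config.boundary_jitter,
                                      config.boundary_jitter + 1,
                                      size=(n_total, 2))
            ivs = [GenomicInterval(iv.chrom,
                                   max(0, iv.start + int(j0)),
                                   iv.end + int(j1), name=iv.name)
                   for iv, (j0, j1) in zip(base_peaks, jit)]
            peaksets[subject] = PeakSet(subject, "ATAC", cond, ivs,
                                        counts.astype(np.int64))

    # --- heterozygous variants inside peaks with allele-biased reads --------
    rng_var = np.random.default_rng(ss_variants)
    subjects = [s for pair in pairs for s in pair]
    n_var = min(config.n_het_variants_in_peaks, n_total)
    # risk variants concentrate in case-specific peaks: a configurable
    # fraction lands there, the rest uniformly over the remaining peaks
    case_idx = np.flatnonzero(label_arr == "case_specific")
    other_idx = np.flatnonzero(label_arr != "case_specific")
    n_in_case = min(len(case_idx),
                    int(round(config.variant_case_peak_bias * n_var)))
    n_other = min(len(other_idx), n_var - n_in_case)
    var_peak_idx = np.concatenate([
        rng_var.choice(case_idx, size=n_in_case, replace=False),
        rng_var.choice(other_idx, size=n_other, replace=False)])
    var_peak_idx.sort()
    n_var = len(var_peak_idx)
    variants: list[VariantRecord] = []
    variant_imbalance: dict[str, tuple[bool, str]] = {}
    allelic_rows: list[dict] = []
    for v, pk_idx in enumerate(var_peak_idx):
        iv = base_peaks[pk_idx]
        margin = config.boundary_jitter + 1
        pos = iv.start + margin + int(rng_var.integers(iv.length - 2 * margin))
        ref = BASES[genome[iv.chrom][pos]]
        alt = BASES[(genome[iv.chrom][pos] + 1 + rng_var.integers(3)) % 4]
        vid = f"var{v:04d}"
        genotypes = {}
        for s in subjects:
            u = rng_var.random()
            if u < config.het_probability:
                genotypes[s] = HET
            elif u < config.het_probability + (1 - config.het_probability) / 2:
                genotypes[s] = HOM_REF
            else:
                genotypes[s] = HOM_ALT
        imbalanced = bool(rng_var.random() < config.imbalanced_fraction)
        favored = "ref" if rng_var.integers(2) == 0 else "alt"
        variant_imbalance[vid] = (imbalanced, favored)
        variants.append(VariantRecord(iv.chrom, pos, vid, str(ref), str(alt),
                                      genotypes))
        bias = config.allelic_bias if imbalanced else 0.5
        for s in subjects:
            if genotypes[s] != HET:
                continue
            depth = int(rng_var.poisson(config.mean_depth_at_variant))
            n_ref, n_alt = sample_allelic_reads(depth, bias, rng_var, favored)
            allelic_rows.append({"variant_id": vid, "subject_id": s,
                                 "assay": "ATAC", "n_ref": n_ref,
                                 "n_alt": n_alt})

    # --- gene models and expression counts ----------------------------------
    rng_expr = np.random.default_rng(ss_expr)
    case_peak_pool = [iv for iv in base_peaks
                      if peak_labels[iv.name] == "case_specific"]
    genes: list[GeneModel] = []
    up_genes: list[str] = []
    down_genes: list[str] = []
    n_linked = min(config.n_up_genes, len(case_peak_pool))
    linked_peaks = (list(rng_expr.choice(len(case_peak_pool), size=n_linked,
                                         replace=False))
                    if n_linked else [])
    chrom_names = list(config.chrom_lengths)
    for g in range(config.n_genes):
        gid = f"gene{g:04d}"
        length = int(rng_expr.integers(800, 5000))
        strand = "+" if rng_expr.integers(2) == 0 else "-"
        if g < n_linked:  # planted-up genes anchored near case-specific peaks
            pk = case_peak_pool[linked_peaks[g]]
            tss = max(0, pk.start + int(rng_expr.integers(-10_000, 10_000)))
            genes.append(GeneModel(gid, pk.chrom, tss, strand, length))
            up_genes.append(gid)
        else:
            chrom = chrom_names[int(rng_expr.integers(len(chrom_names)))]
            tss = int(rng_expr.integers(config.chrom_lengths[chrom]))
            genes.append(GeneModel(gid, chrom, tss, strand, length))
            if len(up_genes) < config.n_up_genes:
                up_genes.append(gid)
            elif len(down_genes) < config.n_down_genes:
                down_genes.append(gid)
    gene_base = rng_expr.gamma(shape=3.0, scale=config.expression_mean_count / 3.0,
                               size=config.n_genes) + 5.0
    up_mask = np.isin([g.gene_id for g in genes], up_genes)
    down_mask = np.isin([g.gene_id for g in genes], down_genes)
    expression_counts: dict[str, np.ndarray] = {}
    for case_id, ctrl_id in pairs:
        case_mean = gene_base * np.where(up_mask, config.expression_fold, 1.0)
        ctrl_mean = gene_base * np.where(down_mask, config.expression_fold, 1.0)
        expression_counts[case_id] = _negbin(rng_expr, case_mean,
                                             config.count_dispersion).astype(np.int64)
        expression_counts[ctrl_id] = _negbin(rng_expr, ctrl_mean,
                                             config.count_dispersion).astype(np.int64)

    truth = GroundTruth(peak_labels, motif_planted, planted_positions,
                        variant_imbalance, up_genes, down_genes)
    return CohortBundle(config, genome, base_peaks, peaksets, pairs, variants,
                        allelic_rows, genes, expression_counts, truth)


# ---------------------------------------------------------------------------
# Fixture directory serialization
# ---------------------------------------------------------------------------

def write_cohort(bundle: CohortBundle, outdir: str | Path) -> Path:
    """Serialize the bundle as the plain-text fixture directory the CLI and
    pipeline consume: per-subject BED + count TSV, cohort VCF, genome FASTA,
    allelic-count TSV, gene table, expression counts, and ground-truth JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for subject, ps in bundle.peaksets.items():
        write_bed(outdir / f"{subject}.peaks.bed", ps.intervals)
        with open(outdir / f"{subject}.counts.tsv", "w") as fh:
            fh.write("peak_id\tcount\n")
            for iv, c in zip(ps.intervals, ps.counts):
                fh.write(f"{iv.name}\t{int(c)}\n")

    with open(outdir / "genome.fa", "w") as fh:
        fh.write(bundle.genome_fasta())

    subjects = [s for pair in bundle.pairs for s in pair]
    with open(outdir / "cohort.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in bundle.config.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(subjects) + "\n")
        gt_code = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", "missing": "./."}
        for var in sorted(bundle.variants, key=lambda v: (v.chrom, v.pos)):
            gts = "\t".join(gt_code[var.genotypes[s]] for s in subjects)
            fh.write(f"{var.chrom}\t{var.pos + 1}\t{var.id}\t{var.ref_allele}\t"
                     f"{var.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n")

    with open(outdir / "allelic_counts.tsv", "w") as fh:
        fh.write("variant_id\tsubject_id\tassay\tn_ref\tn_alt\n")
        for row in bundle.allelic_counts:
            fh.write(f"{row['variant_id']}\t{row['subject_id']}\t{row['assay']}\t"
                     f"{row['n_ref']}\t{row['n_alt']}\n")

    with open(outdir / "genes.tsv", "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\tlength_bp\n")
        for g in bundle.genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\t{g.length_bp}\n")

    with open(outdir / "expression_counts.tsv", "w") as fh:
        fh.write("gene_id\t" + "\t".join(subjects) + "\n")
        for i, g in enumerate(bundle.genes):
            row = "\t".join(str(int(bundle.expression_counts[s][i]))
                            for s in subjects)
            fh.write(f"{g.gene_id}\t{row}\n")

    # proximity-grouped risk loci (LD-block-like: variants within 100 kb share
    # a locus), the unit of counting for overlap enrichment
    with open(outdir / "risk_loci.tsv", "w") as fh:
        fh.write("locus_id\tchrom\tpos\tvariant_id\n")
        for var in sorted(bundle.variants, key=lambda v: (v.chrom, v.pos)):
            lid = f"L_{var.chrom}_{var.pos // 100_000:03d}"
            fh.write(f"{lid}\t{var.chrom}\t{var.pos}\t{var.id}\n")

    with open(outdir / "motif.pfm", "w") as fh:
        fh.write(">NFKB_p50_like\n")
        fh.write("Pos\tA\tC\tG\tT\n")
        for j, row in enumerate(DEFAULT_MOTIF_COUNTS, start=1):
            fh.write(f"{j}\t" + "\t".join(f"{v:g}" for v in row) + "\n")

    with open(outdir / "ground_truth.json", "w") as fh:
        fh.write(bundle.truth.to_json())

    with open(outdir / "pairs.tsv", "w") as fh:
        fh.write("case\tcontrol\n")
        for case_id, ctrl_id in bundle.pairs:
            fh.write(f"{case_id}\t{ctrl_id}\n")

    return outdir
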