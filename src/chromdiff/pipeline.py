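"""End-to-end orchestration of the matched-pair cohort workflow.

Stages run in dependency order on a cohort manifest: per-pair differential
peaks -> cross-pair consistency -> risk-locus overlap enrichment against each
subject's peaks -> motif contrast between the consistent peak sets -> allelic
accessibility calls -> expression integration.  One global seed fans out to
per-stage child seeds by stable hashing of the stage name, so reruns with an
identical manifest are byte-identical.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (ConfigurationError, GenomicInterval, PeakSet, merge_union,
                   read_bed_intervals, read_counts_tsv, read_vcf_genotypes)
from .diffpeaks import PairwiseDifferentialResult, pairwise_differential
from .consistency import (attach_pair_labels, cluster_across_subjects,
                          clusters_to_frame, consistent_specific,
                          exclusive_consistent)
from .reli import correct_pvalues, read_locus_map, reli_enrichment, results_to_frame
from .motifs import extract_sequences, motif_enrichment, pwm_from_counts, read_pwm
from .allelic import (aggregate_variants, call_allelic, candidate_variants,
                      read_allelic_counts, score_records, summarize)
from .expression import (consistent_genes, fpkm_table, pairwise_de,
                         read_gene_table, window_overlap)

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "fc_threshold": 1.5,
    "p_threshold": 0.05,
    "min_pairs": 3,
    "ars_threshold": 0.4,
    "reli_iterations": 2000,
    "motif_alpha": 1e-4,
    "expression_fc": 1.5,
    "window_bp": 100_000,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage child seed: crc32 of the stage name mixed with the seed."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31)


@dataclass
class CohortManifest:
    pairs: list[tuple[str, str]]
    peaks: dict[str, Path]
    counts: dict[str, Path]
    vcf: Path | None = None
    genome: Path | None = None
    allelic_counts: Path | None = None
    genes: Path | None = None
    expression_counts: Path | None = None
    risk_loci: Path | None = None
    pwm: Path | None = None
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    seed: int = 0

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params or {})
        self.params = merged
        subjects = [s for pair in self.pairs for s in pair]
        if len(set(subjects)) != len(subjects):
            raise ConfigurationError("pairing must be a bijection over subjects")
        for s in subjects:
            for table, label in ((self.peaks, "peaks"), (self.counts, "counts")):
                if s not in table:
                    raise ConfigurationError(f"no {label} path for subject {s}")
        for p in [*self.peaks.values(), *self.counts.values(), self.vcf,
                  self.genome, self.allelic_counts, self.genes,
                  self.expression_counts, self.risk_loci, self.pwm]:
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"referenced path does not exist: {p}")

    @classmethod
    def from_dir(cls, fixture_dir: str | Path, seed: int = 0,
                 params: dict | None = None) -> "CohortManifest":
        """Build a manifest from the fixture directory layout the simulator writes."""
        d = Path(fixture_dir)
        pairs_df = pd.read_csv(d / "pairs.tsv", sep="\t")
        pairs = [(str(r.case), str(r.control)) for r in pairs_df.itertuples(index=False)]
        subjects = [s for pair in pairs for s in pair]

        def opt(name: str) -> Path | None:
            p = d / name
            return p if p.exists() else None

        return cls(pairs=pairs,
                   peaks={s: d / f"{s}.peaks.bed" for s in subjects},
                   counts={s: d / f"{s}.counts.tsv" for s in subjects},
                   vcf=opt("cohort.vcf"), genome=opt("genome.fa"),
                   allelic_counts=opt("allelic_counts.tsv"),
                   genes=opt("genes.tsv"),
                   expression_counts=opt("expression_counts.tsv"),
                   risk_loci=opt("risk_loci.tsv"), pwm=opt("motif.pfm"),
                   params=params or {}, seed=seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortManifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent

        def resolve(v):
            return (base / v) if v is not None else None

        return cls(pairs=[tuple(p) for p in raw["pairs"]],
                   peaks={s: resolve(p) for s, p in raw["peaks"].items()},
                   counts={s: resolve(p) for s, p in raw["counts"].items()},
                   vcf=resolve(raw.get("vcf")), genome=resolve(raw.get("genome")),
                   allelic_counts=resolve(raw.get("allelic_counts")),
                   genes=resolve(raw.get("genes")),
                   expression_counts=resolve(raw.get("expression_counts")),
                   risk_loci=resolve(raw.get("risk_loci")),
                   pwm=resolve(raw.get("pwm")),
                   params=raw.get("params") or {}, seed=int(raw.get("seed", 0)))


@dataclass
class RunResult:
    manifest: CohortManifest
    peaksets: dict[str, PeakSet]
    pairwise: dict[str, PairwiseDifferentialResult]
    clusters_frame: pd.DataFrame
    consistent_case: set[str]
    consistent_control: set[str]
    case_only: set[str]
    reli_frame: pd.DataFrame | None
    motif_contrast: dict | None
    allelic_long: pd.DataFrame | None
    allelic_matrix: pd.DataFrame | None
    expression_calls: pd.DataFrame | None
    consistent_up: set[str]
    consistent_down: set[str]
    window_report: dict
    report_text: str = ""


def _load_peaksets(manifest: CohortManifest) -> dict[str, PeakSet]:
    peaksets = {}
    for pair_idx, (case_id, ctrl_id) in enumerate(manifest.pairs):
        for subject, cond in ((case_id, "case"), (ctrl_id, "control")):
            ivs = read_bed_intervals(manifest.peaks[subject])
            counts_map = read_counts_tsv(manifest.counts[subject])
            counts = np.array([counts_map.get(iv.name, 0) for iv in ivs])
            peaksets[subject] = PeakSet(subject, "ATAC", cond, ivs, counts)
    return peaksets


def run_all(manifest: CohortManifest, outdir: str | Path) -> RunResult:
    """Execute every stage, writing one TSV per stage plus report.txt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = manifest.params
    t0 = time.time()

    # --- stage 1: pairwise differential peaks -------------------------------
    peaksets = _load_peaksets(manifest)
    pairwise: dict[str, PairwiseDifferentialResult] = {}
    for k, (case_id, ctrl_id) in enumerate(manifest.pairs):
        pid = f"pair{k+1}"
        res = pairwise_differential(peaksets[case_id], peaksets[ctrl_id],
                                    pair_id=pid,
                                    fc_threshold=params["fc_threshold"],
                                    p_threshold=params["p_threshold"])
        pairwise[pid] = res
        res.to_frame().to_csv(outdir / f"diffpeaks_{pid}.tsv", sep="\t",
                              index=False, float_format="%.6g")
    logger.info("diffpeaks: %d pairs in %.1fs", len(pairwise), time.time() - t0)

    # --- stage 2: cross-pair consistency ------------------------------------
    clusters = cluster_across_subjects(peaksets)
    attach_pair_labels(clusters, pairwise, manifest.pairs)
    case_set, ctrl_set = consistent_specific(clusters, params["min_pairs"],
                                             n_pairs=len(manifest.pairs))
    case_only = exclusive_consistent(case_set, ctrl_set)
    clusters_frame = clusters_to_frame(clusters, case_set, ctrl_set)
    clusters_frame.to_csv(outdir / "consistency.tsv", sep="\t", index=False)
    cluster_by_id = {cl.cluster_id: cl for cl in clusters}

    # --- stage 3: risk-locus enrichment against each subject's peaks --------
    reli_frame = None
    if manifest.risk_loci is not None:
        locus_map = read_locus_map(manifest.risk_loci)
        universe = merge_union([iv for ps in peaksets.values()
                                for iv in ps.intervals])
        datasets: dict[str, list[GenomicInterval]] = {
            s: peaksets[s].intervals for s in sorted(peaksets)}
        if case_set:
            datasets["consistent_case"] = [cluster_by_id[c].interval
                                           for c in sorted(case_set)]
        if ctrl_set:
            datasets["consistent_control"] = [cluster_by_id[c].interval
                                              for c in sorted(ctrl_set)]
        results = []
        for dataset_id, ivs in datasets.items():
            results.append(reli_enrichment(
                locus_map, ivs, universe,
                n_iterations=params["reli_iterations"],
                seed=stage_seed(manifest.seed, f"reli:{dataset_id}"),
                dataset_id=dataset_id))
        correct_pvalues(results)
        reli_frame = results_to_frame(results)
        reli_frame.to_csv(outdir / "reli.tsv", sep="\t", index=False,
                          float_format="%.6g")

    # --- stage 4: motif contrast between consistent peak sets ---------------
    motif_contrast = None
    if manifest.genome is not None and (case_set or ctrl_set):
        from pyfaidx import Fasta

        genome = Fasta(str(manifest.genome))
        pwm = (read_pwm(manifest.pwm) if manifest.pwm is not None
               else _default_pwm())
        fg_ivs = [cluster_by_id[c].interval for c in sorted(case_set)]
        bg_ivs = [cluster_by_id[c].interval for c in sorted(ctrl_set)]
        if fg_ivs and bg_ivs:
            enr = motif_enrichment(extract_sequences(genome, fg_ivs),
                                   extract_sequences(genome, bg_ivs), pwm,
                                   alpha=params["motif_alpha"])
            motif_contrast = {"motif_id": enr.motif_id,
                              "fg_fraction": enr.fg_hit_fraction,
                              "bg_fraction": enr.bg_hit_fraction,
                              "p": enr.p_value, "odds_ratio": enr.odds_ratio,
                              "fg_n": enr.fg_n, "bg_n": enr.bg_n}
            pd.DataFrame([motif_contrast]).to_csv(
                outdir / "motif_contrast.tsv", sep="\t", index=False,
                float_format="%.6g")

    # --- stage 5: allelic accessibility -------------------------------------
    allelic_long = allelic_matrix = None
    if manifest.vcf is not None and manifest.allelic_counts is not None:
        subjects = [s for pair in manifest.pairs for s in pair]
        variants = read_vcf_genotypes(manifest.vcf, subjects)
        candidate_keys = set()
        for subject in subjects:
            for v in candidate_variants(variants, peaksets[subject], subject):
                candidate_keys.add((v.id, subject))
        records = [r for r in read_allelic_counts(manifest.allelic_counts)
                   if (r.variant_id, r.subject_id) in candidate_keys
                   and r.n_total >= 1]
        call_allelic(score_records(records), params["ars_threshold"])
        allelic_matrix = aggregate_variants(records, subjects)
        allelic_long = pd.DataFrame(
            [{"variant_id": r.variant_id, "subject_id": r.subject_id,
              "assay": r.assay, "n_ref": r.n_ref, "n_alt": r.n_alt,
              "strong_allele": r.strong_allele, "p_hat": r.p_hat, "m": r.m,
              "binomial_p": r.binomial_p, "ars": r.ars,
              "is_allelic": r.is_allelic} for r in records])
        allelic_long.to_csv(outdir / "allelic.tsv", sep="\t", index=False,
                            float_format="%.6g")
        allelic_matrix.to_csv(outdir / "allelic_matrix.tsv", sep="\t")

    # --- stage 6: expression integration ------------------------------------
    expression_calls = None
    up_set: set[str] = set()
    down_set: set[str] = set()
    window_report: dict = {}
    if manifest.genes is not None and manifest.expression_counts is not None:
        genes = read_gene_table(manifest.genes)
        counts = pd.read_csv(manifest.expression_counts, sep="\t",
                             index_col="gene_id")
        fpkms = fpkm_table(counts, genes)
        calls = {}
        for k, (case_id, ctrl_id) in enumerate(manifest.pairs):
            calls[f"pair{k+1}"] = pairwise_de(fpkms[case_id], fpkms[ctrl_id],
                                              fc=params["expression_fc"])
        expression_calls = pd.DataFrame(calls, index=fpkms.index)
        expression_calls.to_csv(outdir / "expression_calls.tsv", sep="\t")
        up_set, down_set = consistent_genes(expression_calls,
                                            params["min_pairs"])
        all_peaks = merge_union([iv for ps in peaksets.values()
                                 for iv in ps.intervals])
        case_spans = [cluster_by_id[c].interval for c in sorted(case_set)]
        up_genes = [g for g in genes if g.gene_id in up_set]
        if up_genes:
            frac_all, _ = window_overlap(up_genes, all_peaks,
                                         params["window_bp"])
            window_report["up_genes_vs_all_peaks"] = frac_all
            if case_spans:
                frac_case, _ = window_overlap(up_genes, case_spans,
                                              params["window_bp"])
                window_report["up_genes_vs_case_specific_peaks"] = frac_case
        other_genes = [g for g in genes
                       if g.gene_id not in up_set and g.gene_id not in down_set]
        if other_genes and case_spans:
            frac_other, _ = window_overlap(other_genes, case_spans,
                                           params["window_bp"])
            window_report["other_genes_vs_case_specific_peaks"] = frac_other

    result = RunResult(manifest, peaksets, pairwise, clusters_frame,
                       case_set, ctrl_set, case_only, reli_frame,
                       motif_contrast, allelic_long, allelic_matrix,
                       expression_calls, up_set, down_set, window_report)
    result.report_text = make_report(result)
    (outdir / "report.txt").write_text(result.report_text)
    logger.info("pipeline complete in %.1fs", time.time() - t0)
    return result


def _default_pwm():
    from .simulate import DEFAULT_MOTIF_COUNTS
    return pwm_from_counts("NFKB_p50_like", DEFAULT_MOTIF_COUNTS)


def make_report(result: RunResult) -> str:
    """Human-readable summary; every number is recomputable from the stage TSVs."""
    m = result.manifest
    lines = [
        "cohort analysis report",
        f"version: {__version__}",
        f"seed: {m.seed}",
        "parameters: " + ", ".join(f"{k}={v}" for k, v in sorted(m.params.items())),
        "",
        "[1] pairwise differential peaks",
    ]
    for pid in sorted(result.pairwise):
        counts = result.pairwise[pid].label_counts()
        total = sum(counts.values())
        pct = {k: 100.0 * v / total for k, v in counts.items()}
        lines.append(
            f"  {pid}: n={total} shared={pct['shared']:.1f}% "
            f"case_specific={pct['case_specific']:.1f}% "
            f"control_specific={pct['control_specific']:.1f}%")
    lines += [
        "",
        "[2] cross-pair consistency",
        f"  clusters: {len(result.clusters_frame)}",
        f"  consistently case-specific: {len(result.consistent_case)}",
        f"  consistently control-specific: {len(result.consistent_control)}",
        f"  case-only (exclusive): {len(result.case_only)}",
        f"  case/control consistent overlap: "
        f"{len(result.consistent_case & result.consistent_control)}",
        "",
        "[3] risk-locus enrichment",
    ]
    if result.reli_frame is None:
        lines.append("  no risk-locus table supplied")
    else:
        for r in result.reli_frame.itertuples(index=False):
            lines.append(f"  {r.dataset}: overlap={r.overlap} z={r.z:.2f} "
                         f"p_corrected={r.p_corrected:.3g} "
                         f"enrichment={r.enrichment:.2f}")
    lines += ["", "[4] motif contrast (consistent case vs control peaks)"]
    if result.motif_contrast is None:
        lines.append("  not run (missing genome or empty consistent sets)")
    else:
        c = result.motif_contrast
        lines.append(f"  {c['motif_id']}: fg={100*c['fg_fraction']:.1f}% "
                     f"(n={c['fg_n']}) bg={100*c['bg_fraction']:.1f}% "
                     f"(n={c['bg_n']}) p={c['p']:.3g}")
    lines += ["", "[5] allelic accessibility"]
    if result.allelic_long is None or len(result.allelic_long) == 0:
        lines.append("  zero candidate heterozygous in-peak measurements")
    else:
        n_allelic = int(result.allelic_long["is_allelic"].sum())
        n_var = result.allelic_long.loc[result.allelic_long["is_allelic"],
                                        "variant_id"].nunique()
        opp = summarize(result.allelic_matrix)["n_opportunities"].sum()
        lines.append(f"  opportunities (het-in-peak cells): {int(opp)}")
        lines.append(f"  allelic calls: {n_allelic} at {n_var} variants")
    lines += ["", "[6] expression integration"]
    if result.expression_calls is None:
        lines.append("  no expression data supplied")
    else:
        lines.append(f"  consistently up: {len(result.consistent_up)}  "
                     f"consistently down: {len(result.consistent_down)}")
        for key, frac in sorted(result.window_report.items()):
            lines.append(f"  window overlap {key}: {100*frac:.1f}%")
    return "\n".join(lines) + "\n"
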