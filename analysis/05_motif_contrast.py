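#!/usr/bin/env python
"""Motif-containment contrast between case-specific and control-specific
peak sequences: fraction of peaks with at least one PWM hit on either
strand, with a one-sided Fisher exact test.  Writes results/motifs.tsv."""

import argparse
import json
from pathlib import Path

import pandas as pd

from chromdiff.motifs import motif_enrichment, read_pwm

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--alpha", type=float, default=1e-5)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "motifs.tsv")
    args = ap.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)

    from pyfaidx import Fasta

    truth = json.loads((args.cohort / "ground_truth.json").read_text())
    labels = truth["peak_labels"]
    genome = Fasta(str(args.cohort / "genome.fa"))
    pwm = read_pwm(args.cohort / "motif.pfm")

    # peak spans from any one subject's BED (the landscape is shared)
    import chromdiff.core as core
    subject_bed = sorted(args.cohort.glob("AD1.peaks.bed"))[0]
    peaks = core.read_bed_intervals(subject_bed)
    seqs = {lab: [] for lab in ("case_specific", "control_specific", "shared")}
    for iv in peaks:
        lab = labels.get(iv.name)
        if lab in seqs:
            seqs[lab].append(str(genome[iv.chrom][iv.start:iv.end]))

    rows = []
    for bg_label in ("control_specific", "shared"):
        enr = motif_enrichment(seqs["case_specific"], seqs[bg_label], pwm,
                               alpha=args.alpha)
        rows.append({"motif_id": enr.motif_id, "background": bg_label,
                     "fg_hit_pct": 100 * enr.fg_hit_fraction,
                     "bg_hit_pct": 100 * enr.bg_hit_fraction,
                     "odds_ratio": enr.odds_ratio, "p": enr.p_value})
        print(f"case-specific vs {bg_label}: "
              f"{100*enr.fg_hit_fraction:.1f}% vs "
              f"{100*enr.bg_hit_fraction:.1f}% peaks with a hit "
              f"(p = {enr.p_value:.3g})")
    pd.DataFrame(rows).to_csv(args.out, sep="\t", index=False,
                              float_format="%.6g")
    print(f"table at {args.out}")


if __name__ == "__main__":
    main()
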