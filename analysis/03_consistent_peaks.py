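#!/usr/bin/env python
"""Aggregate pairwise labels across the six matched pairs: peaks specific in
at least three pairs become consistently case- or control-specific calls.
Writes the cluster table to results/consistency.tsv."""

import argparse
from pathlib import Path

from chromdiff.consistency import (attach_pair_labels, cluster_across_subjects,
                                   clusters_to_frame, consistent_specific,
                                   exclusive_consistent)
from chromdiff.diffpeaks import pairwise_differential
from chromdiff.pipeline import CohortManifest, _load_peaksets

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--min-pairs", type=int, default=3)
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "consistency.tsv")
    args = ap.parse_args()

    manifest = CohortManifest.from_dir(args.cohort)
    peaksets = _load_peaksets(manifest)
    results = {f"pair{k+1}": pairwise_differential(peaksets[c], peaksets[t],
                                                   f"pair{k+1}")
               for k, (c, t) in enumerate(manifest.pairs)}
    clusters = cluster_across_subjects(peaksets)
    attach_pair_labels(clusters, results, manifest.pairs)
    case_set, ctrl_set = consistent_specific(clusters, args.min_pairs,
                                             n_pairs=len(manifest.pairs))
    case_only = exclusive_consistent(case_set, ctrl_set)
    frame = clusters_to_frame(clusters, case_set, ctrl_set)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out, sep="\t", index=False)

    print(f"{len(clusters)} cross-subject peak clusters")
    print(f"consistently case-specific (>= {args.min_pairs} pairs): "
          f"{len(case_set)}")
    print(f"consistently control-specific: {len(ctrl_set)}")
    print(f"case-only (not consistently control): {len(case_only)}")
    print(f"overlap of the two consistent sets: {len(case_set & ctrl_set)}")
    print(f"table at {args.out}")


if __name__ == "__main__":
    main()
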