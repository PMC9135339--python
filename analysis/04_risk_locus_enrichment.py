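#!/usr/bin/env python
"""Simulation-null overlap enrichment of the risk-variant loci against each
subject's peaks and against the consistent-specific peak sets, with the
open-chromatin union as the relocation universe (2000 iterations).
Writes results/reli.tsv."""

import argparse
from pathlib import Path

from chromdiff.pipeline import CohortManifest, run_all

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--iters", type=int, default=2000)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "reli_run")
    args = ap.parse_args()

    manifest = CohortManifest.from_dir(args.cohort, seed=args.seed,
                                       params={"reli_iterations": args.iters})
    result = run_all(manifest, args.out)
    frame = result.reli_frame
    frame.to_csv(ROOT / "results" / "reli.tsv", sep="\t", index=False,
                 float_format="%.6g")
    print(frame.to_string(index=False))
    sig = frame[frame["p_corrected"] < 0.05]
    print(f"\n{len(sig)} of {len(frame)} datasets significantly enriched "
          f"after correction; the consistent-case set carries the planted "
          f"risk-variant concentration.")


if __name__ == "__main__":
    main()
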