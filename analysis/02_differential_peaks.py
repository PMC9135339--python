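#!/usr/bin/env python
"""Pairwise case-vs-control differential peak analysis for every matched
pair: M-A normalization on common peaks, Audic-Claverie significance, and
shared/case-specific/control-specific classification at FC > 1.5, p < 0.05.
Writes one table per pair under results/diffpeaks/."""

import argparse
from pathlib import Path

from chromdiff.diffpeaks import pairwise_differential
from chromdiff.pipeline import CohortManifest, _load_peaksets

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "diffpeaks")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    manifest = CohortManifest.from_dir(args.cohort)
    peaksets = _load_peaksets(manifest)
    for k, (case_id, ctrl_id) in enumerate(manifest.pairs):
        pid = f"pair{k+1}"
        res = pairwise_differential(peaksets[case_id], peaksets[ctrl_id], pid)
        res.to_frame().to_csv(args.out / f"{pid}.tsv", sep="\t", index=False,
                              float_format="%.6g")
        c = res.label_counts()
        total = sum(c.values())
        print(f"{pid} ({case_id} vs {ctrl_id}): "
              f"shared {100*c['shared']/total:.1f}%  "
              f"case-specific {100*c['case_specific']/total:.1f}%  "
              f"control-specific {100*c['control_specific']/total:.1f}%  "
              f"(baseline a={res.a:+.3f}, b={res.b:+.3f})")
    print(f"tables under {args.out}")


if __name__ == "__main__":
    main()
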