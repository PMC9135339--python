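# chromdiff

Case/control regulatory-genomics inference for matched-pair cohorts:
pairwise differential chromatin accessibility, cross-pair consistency
calling, simulation-null risk-locus overlap enrichment, transcription-factor
motif contrasts, allele-dependent accessibility scoring, and expression/peak
window integration — validated end-to-end on synthetic cohorts with planted
ground truth.

## Who this is for

Epigenomics studies that compare a handful of cases against demographically
matched controls (ATAC-seq or ChIP-seq peaks plus genotypes and RNA-seq)
face a common chain of questions: which peaks differ within each matched
pair, which differences are consistent across pairs, whether disease risk
variants concentrate in the disease-specific open chromatin, which
transcription-factor motifs distinguish the specific peak sets, and whether
accessibility at heterozygous risk variants depends on the allele. This
package implements that chain as a tested, seedable library with a thin CLI,
plus a cohort simulator so every stage can be validated against known truth.

## The statistics at the core

- **Pairwise differential peaks.** Matched peaks in M–A coordinates
  (M = log₂ case/control count ratio, A = ½·log₂ of the count product,
  pseudocount ½), a Theil–Sen baseline M = a + b·A fitted on common peaks,
  and an Audic–Claverie posterior-predictive p-value on library-scaled
  counts. A peak is case-specific iff 2^{M_norm} > 1.5 and p < 0.05.
- **Consistency.** Single-linkage ≥ 1 bp clustering of peaks across
  subjects; a cluster is consistently specific when labeled specific in
  ≥ 3 of 6 pairs.
- **Risk-locus enrichment.** Observed count of risk loci with ≥ 1 variant
  in ≥ 1 peak, against a null that relocates each locus as a rigid block
  uniformly over an open-chromatin universe (2,000 iterations):
  z = (obs − μ₀)/σ₀, one-sided normal p, fold = obs/μ₀.
- **Motif contrast.** Log-odds PWM scanning with an exact
  dynamic-programming score cutoff (per-position tail ≤ α under the
  background); one-sided Fisher exact test on the fraction of peaks
  containing ≥ 1 hit.
- **Allelic accessibility.** At heterozygous in-peak variants with n reads
  and strong-allele fraction p̂: imbalance m = 2|p̂ − ½|, exact binomial
  test vs ½, and a reproducibility score
  ars = m · min(1, log₁₀(n+1)/2), called allelic when ars ≥ 0.4.
- **Expression.** FPKM, strict pairwise 1.5-fold calls, the same
  ≥ 3-pairs consistency rule, ±100-kb TSS-window overlap with peak sets,
  and a hypergeometric over-representation test.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Generate a six-pair cohort and run the whole chain (the numbered scripts
under `analysis/` run the stages individually):

```
python analysis/01_simulate_cohort.py --seed 1
python analysis/08_full_pipeline.py --seed 1
```

The first command writes a fixture under `results/cohort/` and prints

```
6 matched pairs, 2200 peak loci (2000 shared, 100 case-specific, 100 control-specific)
200 heterozygous-capable variants, 1476 het-in-peak read measurements
300 genes (20 planted up, 20 planted down)
```

The pipeline report then shows, per pair, label fractions like

```
pair1: n=2200 shared=86.7% case_specific=7.0% control_specific=6.4%
```

— most peaks shared within a matched pair, the planted 3-fold specific
peaks plus a small false-positive margin called specific. The consistency
stage recovers the planted peaks (`consistently case-specific: 100`), and
the enrichment stage finds the planted concentration of risk variants in
case-specific open chromatin while the per-subject datasets stay null:

```
CTL6:            overlap=30/30 z=0.53  p_corrected=1        enrichment=1.01
consistent_case: overlap=26/30 z=11.68 p_corrected=1.07e-30 enrichment=6.55
```

The motif stage reports the planted case-biased motif
(`fg=24.0% bg=3.0%` of peaks containing a hit, Fisher p ≈ 7e-06 against
control-specific peaks), and the allelic stage calls the planted imbalanced
heterozygotes (`681 allelic instances at 106 variants` out of 1,476
het-in-peak measurements). Every run is stamped with its seed and
parameters, and rerunning with the same seed reproduces all outputs
byte-for-byte.

The same stages are available as a CLI (`chromdiff simulate`,
`chromdiff diffpeaks`, `chromdiff reli`, `chromdiff motifs`,
`chromdiff allelic`, `chromdiff pipeline run`).

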