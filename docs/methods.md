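# Methods

This note documents the models, statistics, and design choices behind each
stage of the package, the conditions the synthetic cohort generator
emulates, and the known limitations of both.

## Coordinate and overlap conventions

All internal coordinates are 0-based half-open (the BED convention); VCF
positions are converted by −1 on read so only one convention exists
package-wide. "Overlap" always means at least one shared base pair;
touching half-open intervals do not overlap. Clustering and matching
functions expose a minimum-overlap option but default to the 1-bp rule,
because peak-matching practice in case/control ATAC analyses rarely states
a fraction and the 1-bp rule is the least surprising default. Sorting ties
are broken by (end, name) so every output ordering is deterministic.

## Pairwise differential peaks (M–A model)

For one matched case/control pair, peaks present in both subjects
("common", matched greedily by largest shared bp, ties to the leftmost) are
placed in M–A coordinates with a 0.5 pseudocount:

    M = log2((x_case + ½) / (x_ctrl + ½)),
    A = ½·log2((x_case + ½)(x_ctrl + ½)).

A robust straight line M = a + b·A is fitted on common peaks by Theil–Sen
(least squares available by flag); every peak — common or unique — is then
rescaled to M_norm = M − (a + b·A). The robust fit resists leverage from
genuinely differential peaks, and the common-peak baseline encodes the
assumption that most of the landscape is shared, so the median M_norm over
common peaks is ≈ 0.

Significance uses an Audic–Claverie-style Bayesian posterior-predictive
test on library-scaled counts: conditioned on the case count x with library
N1, the control count is negative-binomial with size x + 1 and success
probability N1/(N1+N2); doubling the smaller tail gives a directional
p-value. Because that tail is not exchange-symmetric, the pinned statistic
averages the two conditioning orientations, which makes p(x, y) = p(y, x)
exact for equal libraries (verified against direct tail summation in the
tests). Library sizes default to each subject's total counts, so no
external depth metadata is needed.

A peak is case-specific when 2^{M_norm} > 1.5 (strict) and p < 0.05,
control-specific symmetrically, shared otherwise. Peaks found in only one
subject enter the same rule with a pseudocounted zero on the absent side,
so strong single-subject peaks can be called specific. Swapping the two
inputs swaps the case/control labels exactly.

The Poisson-family test is deliberately the model used by the standard
pairwise differential-peak tool for this design (one subject per arm, no
replicates). It is anti-conservative when counts are strongly
overdispersed; the generator's dispersion parameter exists precisely to
exercise that failure mode (see Limitations).

## Cross-pair consistency

Peaks from all subjects are clustered by single-linkage ≥ 1 bp overlap; for
interval data this equals connected components of the overlap graph and is
computed by one sorted sweep. Each cluster receives one label per pair:
specific if any member peak of that pair carries the specific label and
none carries the opposite one, shared on conflict, absent when the pair has
no member peak (absent never counts toward a threshold). A cluster is
*consistently* case-specific when labeled case-specific in ≥ 3 pairs
(configurable); the exclusive set additionally removes clusters that are
also consistently control-specific. Raising the pair threshold can only
shrink the consistent sets (tested). Disjointness of the two consistent
sets is reported as a statistic, not assumed.

## Risk-locus overlap enrichment (relocation null)

Risk variants arrive grouped into independent loci (LD-block-like units); a
locus counts as overlapped when ≥ 1 member variant lies inside ≥ 1 peak,
and at most once. The null relocates each locus as a rigid block — the
first variant anchors at a position drawn uniformly over the base pairs of
a merged open-chromatin "universe", member offsets preserved (offsets may
exit the universe; allowed and flagged). The randomized unit is the locus,
not the peak set: this preserves the peak structure of the tested dataset
and matches the locus count of the input. 2,000 iterations give a null
mean and sd, hence z = (obs − mean)/sd, a one-sided upper-tail normal p
(enrichment direction only), and fold = obs/mean. A zero-sd null is flagged
degenerate with p = 1 (or the machine minimum if the observation exceeds
the mean). Bonferroni is the default correction across datasets,
Benjamini–Hochberg by flag.

Calibration: with variants placed uniformly over the universe the p-values
are approximately uniform; the tests verify this with a KS check over 200
seeded trials using 150 single-variant loci per trial — enough loci that
the discreteness of the overlap count does not dominate the p distribution.
The normal approximation is the method's own assumption; small locus counts
make p discrete (and the KS check inappropriate), which is why the toy
3-locus case is instead checked against the exact Binomial(3, ½) oracle.

## Motif scanning and enrichment

PWMs are read from Cis-BP-style (rows = positions) or JASPAR-style (rows =
bases) text, normalized to probabilities with a 1e-3 pseudocount. Scanning
is standard log-odds: score(i, strand) = Σ_j log2(p_motif(base)/p_bg(base)),
the minus strand scored on the reverse complement, N-containing windows at
−∞. The hit cutoff is the smallest achievable score whose background tail
probability is ≤ alpha (default 1e-4 per position, a community-standard hit
rate), computed from the exact score distribution by dynamic programming
over positions with merging of numerically identical states; up to width
~9 every achievable score is represented exactly (the tests confirm
equality with exhaustive enumeration at widths 4–6), wider matrices fall
back to a 1e-4-granularity grid.

A peak "contains" the motif when ≥ 1 position on either strand reaches the
cutoff; enrichment between two peak sets is the one-sided Fisher exact test
on the 2×2 containment table, direction foreground > background. The
log-odds background defaults to the pooled base composition of both peak
sets. Peak-level containment (rather than hit counts) matches how
percent-of-peaks contrasts are reported for this design.

The generator plants one PWM-sampled instance per selected peak, resampling
(≤ 50 draws, then the consensus) until the instance clears the hit cutoff
at alpha = 1e-5, so planted truth is detectable at any scanning alpha ≥
1e-5 by construction; planting positions keep clear of the peak edges so
per-subject boundary jitter cannot truncate them.

## Allelic accessibility (imbalance + reproducibility score)

Candidates are variants heterozygous in a subject and inside one of that
subject's peaks. At each candidate, with n_ref + n_alt = n reads, the
strong-allele fraction p_hat (ties to the reference; the imbalance is then
zero anyway) gives m = 2·|p_hat − ½| and an exact two-sided binomial test
against ½. The reproducibility score combines imbalance with a saturating
depth term:

    ars = m · min(1, log10(n + 1)/2),

monotone in both arguments, depth-saturating at ~100 reads, thresholded at
0.4 **inclusive**. The published score of this name is a trained composite
whose exact form is not restated in the source material; this surrogate
preserves its stated contract (increasing in total reads and in imbalance,
same threshold and qualitative behavior: 20 reads at 95:5 are called, 4
reads at 100:0 are depth-gated out) and is isolated in one function so an
alternative can be swapped in. At the default conditions (bias 0.85, mean
depth 30) sensitivity is ≈ 0.88–0.93 with a false-call rate ≈ 0.3% on
balanced variants. Per-subject records and a pooled-reads summary are both
available; pooling is descriptive only. Reference-mapping bias is out of
scope because counts arrive as a tabulated pileup, not alignments.

## Expression integration

FPKM = count·10⁹/(length·library). Pairwise differential calls use a bare
fold-change gate, strictly greater than 1.5, on pseudocounted FPKM (0.1,
since zeros are common); no significance test, matching the replicate-free
pairwise design. Consistent gene sets use the same ≥ 3-pairs rule as peaks.
Gene–peak linkage uses a window of ±100 kb around the TSS (gene-body
anchoring by flag; TSS is the default because the linkage of interest is
promoter-proximal regulatory access). A generic one-sided hypergeometric
over-representation test with BH correction covers annotation gene sets;
no ontology database is bundled.

## Synthetic cohort generator

The generator emulates the data structure of a six-pair matched
case/control cohort:

- **Genome**: 3 chromosomes × 1 Mb of uniform random sequence — large
  enough for thousands of non-overlapping 500-bp peaks, small enough for
  seconds-scale tests.
- **Peak landscape**: 2,000 shared + 100 case-specific + 100
  control-specific peak loci on a non-overlapping grid (200-bp gaps);
  per-subject boundaries jittered ±20 bp so cross-subject clustering is
  non-trivial but never merges neighboring loci.
- **Counts**: negative binomial around a per-peak gamma-distributed mean
  (mean ≈ 50 reads); condition-specific peaks get the mean multiplied by
  3.0 in the matching arm of every pair. Dispersion defaults to 0.005
  (variance = μ + 0.005 μ²): mild extra-Poisson technical noise, chosen
  because the pairwise test is a Poisson-family model and because this
  setting reproduces the 86–96% per-pair shared fraction observed in real
  matched-pair ATAC comparisons of this design. Larger dispersions are a
  documented stress for the p-value, not the default condition.
- **Motifs**: a p50-like 10-bp PWM planted in 30% of case-specific peaks
  and 1% of all others, one instance per peak.
- **Variants**: 200 SNVs inside peaks, 30% of them concentrated in
  case-specific peaks (so the locus-enrichment stage has signal to find);
  each subject heterozygous with probability 0.6; half the variants
  imbalanced with the favored allele drawn at probability 0.85 per read,
  depth Poisson(30).
- **Expression**: 300 genes, 20 planted 2.5-fold up in all cases (TSSs
  placed within 10 kb of case-specific peaks) and 20 down; same NB noise.
- **Determinism**: one mandatory seed fans out through spawned
  SeedSequences per stage; identical seeds give byte-identical serialized
  fixtures on any platform (integer-stream sampling only).

What the generator does **not** emulate: read-level fragments and Tn5
insertion bias, LD structure among variants, GC/mappability artifacts,
reference-mapping bias in allelic counts, batch effects, and biological
between-subject variability beyond NB dispersion. Passing tests therefore
demonstrate correctness and calibration of the inference chain under its
own model assumptions — not performance on real sequencing data.

## Problem sizes used in checks

The validation suite runs the full six-pair cohort at 2,200 peak loci, the
relocation null at 2,000 iterations (500 in the repeated-trial calibration
loops), the motif checks on 300+300 peaks, and the allelic calibration on
10⁴ simulated variants; the end-to-end reproducibility check uses a
520-locus cohort. These sizes were chosen to put every estimate's Monte
Carlo error well inside the asserted bounds while keeping the whole suite
in the minutes range.

## Known limitations

- The differential p-value is anti-conservative under strong
  overdispersion (no replicate-based variance estimation by design).
- On the scaled-down genome, ±100-kb TSS windows nearly always overlap the
  dense peak landscape, so the window statistic saturates near 100% there;
  directional contrasts are visible at smaller windows (the tests use
  ±20 kb for that check).
- The reproducibility score is a surrogate with the documented contract,
  not the published trained score.
- The relocation null matches locus count and structure only — not allele
  frequency, SNP density, or distance-to-gene covariates.
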