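# Methods

This note documents the statistical procedures implemented in riberflow,
the defaults and why they were chosen, what the synthetic-data generators
emulate, and the limits of what passing tests demonstrate.

## Count normalization and enrichment testing

Size factors are median-of-ratios: for each sample, the median over
reference features (strictly positive counts in every sample) of the
count divided by the feature's geometric mean across samples.  The median
is taken on the ratio scale (arithmetic midpoint at even counts), matching
the estimator's standard definition.  If no reference feature exists the
normalization is undefined and a `NormalizationError` names the condition.

The enrichment factor is EF = log2(mean normalized count in group A /
same in group B).  The test pseudocount defaults to 0 so the statistic is
unbiased; a reporting pseudocount of 0.5 is used only to display a finite
EF when one group mean is zero.  EF is assumed and documented to be on the
log2 scale throughout (the thresholds 1, 1.5, −1 and the percentile
cutoffs read naturally as log2 fold changes).

p-values come from a deliberately simple negative-binomial Wald surrogate,
not a shrinkage-based DE engine: per-feature method-of-moments dispersion
`alpha = (s² − mu)/mu²` pooled across the two groups (floored at 1e-8,
no shared-trend smoothing), delta-method variance of the log ratio
`(1/mu_A + alpha)/n_A + (1/mu_B + alpha)/n_B`, and the Wald statistic
referred to a **t distribution with n_A + n_B − 2 df** rather than the
normal.  The t reference is the consequential choice: with triplicates the
dispersion is estimated from four residual degrees of freedom, and the
normal reference is markedly anticonservative (about 12% rejections at
nominal 5% in our null simulations) while the t reference is close to
nominal (4%, with near-uniform p-values).  Features that are all-zero in
both groups are flagged, reported with p = 1, and excluded from the BH
adjustment.  BH adjustment is delegated to statsmodels and checked in the
test suite against a brute-force step-up oracle.

Consequence of the simplified engine: data-derived constants from
shrinkage-based analyses (e.g. a 75th-percentile cutoff of exactly 3.03 on
a real dataset) are not expected to be matched numerically; the selection
*procedure* operating on the EF distribution is the reproduced object.

The expression filter counts a feature as detected when its total reads
across the analysis group's samples reach 10 (boundary inclusive).  The
sum-across-samples convention (vs per-sample) is configurable via
`min_reads` and documented here because the alternative is equally
defensible.

## RIP-Seq selection cascade

Stages, with boundary conventions chosen deliberately:

1. candidates: EF **strictly** > 1, adjusted p ≤ 0.05 (inclusive);
2. percentile gate: linear-interpolation (type-7) percentile of the
   candidate EF distribution, default 0.75; pass requires EF strictly
   above the cutoff, so a degenerate all-equal distribution gates nothing;
3. specificity: an RNA is "detected in the control line" when it passes
   the expression filter there *and* has control EF > 0; gated RNAs
   outside that set are specific;
4. rescue of shared RNAs: (case EF / control EF) ≥ 4 with both EFs
   strictly positive (the ratio is meaningless across signs and the
   branch is skipped when the control EF ≤ 0), **or** control EF < −1.
   The `≥ 4` default is configurable to a strict `> 4`.

A literal simultaneous reading of all three rescue conditions (ratio AND
percentile AND negative control EF) is self-contradictory — a control
EF < −1 makes a positive ratio impossible — so the disjunctive reading is
implemented: percentile-gated AND (ratio branch OR negative-EF branch).
The percentile gate applies to rescued RNAs via their case EF (they must
already be above the case cutoff).

The report's accounting law, asserted on every run: `selected = specific
+ rescued` disjointly, and `remaining = gated − specific`.  The miRNA
variant uses EF > 1.5, ratio ≥ 2, negative-EF threshold 0, and no
percentile gate; two p-value presets are shipped (raw p ≤ 0.05, the
default, and adjusted p < 0.1) because both conventions are in
circulation — neither is asserted as canonical.

Biotype-class enrichment is an upper-tail hypergeometric test per class
(population = annotated background, successes = class size, draws =
selected set).

## Intron retention and reversal

IR of an intron in a sample = (intron reads / intron bp) / (sum of exon
reads / sum of exon bp over the gene's merged exons).  IR is 0 for a
read-free intron and undefined (NaN, excluded from testing) when the
gene has zero exon signal in that sample.  IR is invariant under uniform
scaling of a sample's counts, so no size-factor step is needed.

Differential retention uses Welch's t-test on replicate IR values (the
variance structure across conditions is not assumed equal), BH-adjusted.
The cross-condition **modulation coefficient** is log2(mean IR_A / mean
IR_B); because no scale is inherent in the bin labels (±1.5, ±2), the
log2 reading was adopted — the bins then read as fold changes — and a
linear-difference mode is available via `scale="linear"`.  Zero means are
floored at the smallest positive IR in the table before the log, keeping
the coefficient finite without per-intron tuning.  A positive coefficient
means more retention, i.e. reduced splicing efficiency, in condition A.

Reversal analysis: among introns with a significant receptor-driven
retention change, binned by modulation coefficient, an event is *reverted*
when its knock-down-contrast modulation has the opposite sign **and** is
itself significant at FDR 0.05 (the significance requirement is the
default and configurable; without it, sign noise among unaffected introns
would inflate reversal fractions by roughly half the non-reverted share).
Empty bins report NaN, never 0.

## Interval statistics

Coordinates are 0-based half-open (BED) everywhere; GTF input is converted
on read.  Proximity uses midpoint-to-midpoint distance with an inclusive
1000 bp window (the anchoring convention is not canonical; an edge-gap
mode would give systematically smaller distances for wide peaks).
"Precise co-localization" means ≥ 1 bp intersection.

The permutation overlap test re-places intervals uniformly within their
chromosomes, preserving lengths and per-chromosome counts (both sets by
default), counts overlapping pairs, and reports the plus-one empirical
p-value `(1 + #{sim ≥ obs}) / (1 + n_sims)` — never exactly zero, and
monotone in the observed overlap.  When the expected null overlap is far
below 1 the count distribution is very discrete and the p-value is
conservative; calibration studies should use sets dense enough for an
expected overlap of several counts.

Segment enrichment compares observed bp overlap per segment class with
the mean over uniform re-placements (no isochore or gap-aware workspace,
unlike full GAT — fold values are comparable, not identical), two-sided
plus-one p-values, BH q-values across classes, and an `enriched` flag at
fold > 2 and q ≤ 0.05.  A class never hit in the null reports fold NaN,
never infinity.

## Interactome quantification

LFQ values are divided per replicate by the bait's intensity (errors name
the offending replicate), log2-transformed, and tested with a two-sample
statistic `t = (mean_A − mean_B) / (se + s0)` with `s0 = 0.1` on the log2
scale — the SAM/Perseus-style variance-stabilizing constant.  At three
replicates per arm, occasional proteins with near-zero sample variance
otherwise dominate the permutation null with arbitrarily large |t|; s0
bounds their statistics without affecting genuinely variable proteins.
The null distribution enumerates all distinct group-label splits when
there are at most 200 (all C(6,3) = 20 at 3 vs 3), sampling otherwise,
and FDR(t*) is the median over permutations of the null exceedance count
divided by the observed exceedance count at |t| ≥ t*, clipped to 1.
Proteins need two finite values per group to be tested; there is no
imputation.  Bait normalization is idempotent and absorbs any
per-replicate rescaling of the raw intensities.  Dependence summaries
report exact fractions and a half-up-rounded integer percentage.

## Synthetic data: what is emulated, and what is not

All generators derive their randomness from a single seed through named
SeedSequence spawn keys, so a fixed seed reproduces every output byte for
byte and adding a generator never perturbs another's draws.  Counts are
negative binomial with variance `mu + alpha·mu²`; per-sample depth factors
are log-uniform on [1/spread, spread] so size-factor estimation is
non-trivial.  One truth file is written per dataset; tests never re-derive
truth.

Defaults encode the study design the pipeline targets — triplicate
IP/input libraries in a case and a control cell line, triplicate
nascent-RNA libraries in three conditions (wt, receptor-positive,
receptor-positive + knock-down), triplicate LFQ runs per arm — with these
choices:

- `nb_dispersion = 0.02`: well-controlled cell-line replicates.
- `enriched_fraction = 0.05`: a specifically-bound set of a few percent of
  expressed genes, the regime the cascade targets.
- `enrichment_log2fc = 4`: typical of a strongly associated RNA (selected
  sets span EF ≈ 3 to beyond 10); parameter-recovery experiments plant
  EF = 3 explicitly.
- `background_ef_sigma = 1.5`: unplanted genes carry a log-normal
  nonspecific pull-down efficiency, independent per cell line.  This is
  what makes the percentile gate meaningful — with no background spread
  the candidate set collapses onto the planted set and a top-quartile
  gate would discard three quarters of it by construction.  Planted RNAs
  carry the exact effect with no background term, a simplification that
  makes parameter recovery interpretable.  Setting the sigma to 0 yields
  the enrichment test's exact null for calibration studies.
- nascent `coverage_mean = 5` reads/bp and `background_ir = 0.1`: deep
  libraries with baseline co-transcriptional retention; planted introns
  shift retention by ±`ir_shift_log2` (signs alternating), and reversal
  is planted per direction (`reversal_fraction` for retention decreases,
  `reversal_fraction_positive` for increases) so per-bin reversal rates
  are recoverable.
- LFQ `noise_sigma = 0.1` (low-noise replicates), 2-fold planted
  reductions, 5% missingness; the bait's own noise uses a third of
  `noise_sigma` because the bait dominates the pull-down and is quantified
  much more precisely — with equal bait noise, the normalization step
  propagates it to every protein as a column-shared offset and power
  collapses on unlucky replicate draws, which is itself a caution worth
  knowing about bait normalization on real data.

Not emulated: read-level artifacts (FASTQ, alignment, GC and positional
bias), overdispersion trends with expression level, correlated
gene-gene structure, isoform mixtures, peak-width distributions from real
ChIP, intensity-dependent LFQ missingness (missingness here is uniform at
random), and batch effects.  Passing parameter-recovery tests therefore
demonstrates that the estimators recover what the model plants at
realistic depths and replication — not that real libraries satisfy the
model.

## Numerical and degenerate-input conventions

- Percentile: type-7 (linear interpolation), the most common default.
- Strict vs inclusive boundaries follow the stated gates exactly
  (EF > 1 strict, p ≤ 0.05 inclusive, ratio ≥ 4 default-inclusive,
  proximity ≤ 1000 inclusive, detection ≥ 10 inclusive).
- Zero-variance intron pairs are flagged and not tested; both-zero count
  features are flagged with p = 1; empty reversal bins are NaN; absent
  segment classes give fold NaN.
- Modulation bin edges close the [1.5, 2] bin at 2.0 and open (2, ∞), and
  symmetrically on the negative side, so the five bins partition the line.
- Integer percentages round half-up (31/41 → 76%).
- The demo report omits wall-clock time (logged to stderr instead) so
  fixed-seed runs are byte-reproducible; artifacts carry the config hash
  and an unchanged config is a no-op unless forced.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen so
the full suite completes in well under a minute of compute: 200–2000
genes per simulated dataset, 200-seed calibration sweeps, 199–999
permutations for interval tests (the estimator is unchanged at any
n_sims; the CLI defaults remain 100,000 and 10,000 for production use),
and ~300-protein LFQ matrices.  Dataset-scale published totals (tens of
thousands of binding sites or retention events) require the original
sequencing data and are outside what synthetic desk-scale runs reproduce;
the arithmetic relations among those totals are validated instead.

## Known limitations

- The NB-Wald surrogate has no dispersion shrinkage or outlier handling;
  at very low counts its t reference is approximate.
- The specificity split's "detected in control" definition (expression
  filter AND EF > 0) is one of several defensible readings and is
  configurable.
- The permutation overlap test assumes placement anywhere on a chromosome
  is admissible (no mappability or gap masking).
- The SAM-style FDR at 20 enumerable permutations is coarse below about
  0.05/protein-count granularity; with larger designs it sharpens.
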