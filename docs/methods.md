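# Methods

## Problem setting

A cassette exon is an internal exon either included between its flanking
exons or skipped. Its inclusion level Ψ (percent spliced-in) is the fraction
of transcripts carrying the exon, estimated from junction-supporting reads.
Brain development reshapes hundreds of these inclusion levels; in the DM1
frontal cortex a subset reverts toward the prenatal pattern because the
antagonistic regulators MBNL1/2 (adult-promoting) and CELF1
(fetal-promoting) are functionally imbalanced. The package provides the
statistical machinery to (a) find developmentally regulated events, (b) find
disease-dysregulated events, (c) intersect and orient them relative to the
fetal program, and (d) attribute their coordination to the regulator balance
by correlation and partial-correlation analysis — plus a generator of
synthetic cohorts with exactly this structure so every stage can be
validated against ground truth.

## Coordinates and event arithmetic

All genomic coordinates are 1-based and fully inclusive; exon length is
`end − start + 1`. This convention is validated against every row of the
packaged 34-event table at load time. An exon disrupts the reading frame iff
its length is not divisible by three. Unique cassette exons are counted by
merging overlapping skipped-exon intervals per chromosome (identical
intervals and variable 5′/3′ ends collapse together); strand is not modeled
because the table omits it and interval overlap already reproduces the
published exon count. Event ids follow the gene-symbol + single lowercase
variant letter convention (`SORBS1a`). The MISO-style GFF3 annotation writes
one gene and two isoforms (inclusion: upstream + cassette + downstream;
exclusion: flanks only) per event; the packaged table carries no flanking
coordinates, so writing GFF for it requires supplying flanks.

## PSI estimation

For inclusion count I over `inclusion_positions` read positions and
exclusion count E over `exclusion_positions` (defaults 2 and 1 — the
skipped-exon geometry with two inclusion junctions and one skipping
junction when reads are much shorter than exons), counts are
length-normalized, rescaled to preserve the observed total, and the
posterior mean under a uniform Beta(1, 1) prior is reported:
Ψ̂ = (I′ + 1)/(I′ + E′ + 2). The estimator is bounded away from 0/1, returns
the prior mean 0.5 with no reads, and is exactly antisymmetric under
swapping inclusion and exclusion. A full Bayesian read-position model is out
of scope; the posterior mean reproduces its point estimates at realistic
depths (consistency is tested by Monte-Carlo at depth 10⁴ within 0.01).

Detection: an event is detected in a sample when its informative reads
(I + E) reach `min_reads` (default 10 — detection is rarely defined
explicitly in published pipelines, so the threshold is an explicit,
configurable choice here). An event is kept in a dataset only if detected in
**every** sample of that dataset. The synthetic generator emits
isoform-level effective junction counts, so the pipeline estimates their Ψ
with positions (1, 1); the (2, 1) default applies to real junction tables.

## Differential inclusion and empirical FDR

Per event, the two-sided Wilcoxon rank-sum test compares Ψ between groups:
exact enumeration when the combined n ≤ 12 with no ties, otherwise the
normal approximation with tie correction and continuity correction (the
switch is fixed so results are reproducible across inputs). Events with
constant Ψ get p = 1. Significance is the joint rule p < 0.01 and
|ΔΨ| > 0.2; p-values in the transcriptome-wide screen are not
multiplicity-corrected. Instead, the empirical FDR of the whole rule is
estimated by unstratified random shuffling of the group labels across all
samples (default 100 shuffles):
FDR = mean(#significant under shuffling) / max(#significant observed, 1).
The max(·, 1) denominator is a stated convention avoiding division by zero.
When fewer distinct label splits exist than requested shuffles, shuffling
proceeds with replacement and warns. Benjamini–Hochberg adjustment (used for
the targeted group comparisons and all correlation analyses) delegates to
statsmodels.

## Cross-dataset intersection

Sign conventions are fixed package-wide: ΔΨ_dev = prenatal − postnatal,
ΔΨ_DM1 = DM1 − unaffected. An event changed *toward the prenatal pattern*
iff the two deltas share a nonzero sign; opposite signs mean toward the
postnatal pattern; a missing or exactly zero delta gives `unknown` (zero is
measure-zero in practice; treating it as unknown avoids arbitrary
tie-breaks). High confidence = significant in both datasets (joint rule)
with toward-prenatal direction. Overlap enrichment is the hypergeometric
upper tail P(X ≥ k) (one-sided Fisher exact); the universe is the set of
events measured in both datasets after detection filtering and is always
reported next to the p-value. The direction tally supports two criteria:
`both_p` (p < 0.01 in both datasets, the histogram criterion) and `either`
(joint-rule significant in at least one).

## Expression normalization

TMM is reimplemented from its published definition: the reference sample is
the one whose 75th percentile of count proportions is closest to the mean;
per sample, gene-wise M = log2 ratio and A = mean log2 abundance of
library-normalized proportions are computed over genes positive in both
samples; 30% of each M tail and 5% of each A tail are trimmed (average
ranks); the factor is 2^(Σ M/w / Σ 1/w) with binomial delta-method
variances w; factors are rescaled to geometric mean 1. If all M are within
1e-6 of zero, or no genes survive trimming, the factor is 1 (with a warning
in the latter case). Note that multiplying one sample's counts by a constant
leaves M exactly unchanged but shifts the precision weights, so factors are
scale-stable only to ~1e-3 — the same behavior as the reference
implementation of the method. log2-CPM is
log2((count + prior)/(lib × factor + 2·prior) × 10⁶) with prior 0.5; the
pseudocount affects values at the 4th decimal for counts ≥ 100. An optional
minimum-count gene filter before TMM exists but defaults to off. Group fold
changes are differences of group means on the log2-CPM scale.

## Correlation analyses

Spearman's rank correlation is used throughout — inclusion levels are
bounded, typically skewed, and often nonlinear in their drivers, so a rank
statistic is the fixed design choice. p-values use the t-approximation with
n − 2 df. Partial Spearman correlations rank-transform all variables and
normalize the inverse of the rank-correlation matrix,
r_xy·Z = −P_xy/√(P_xx P_yy); with |Z| = 1 this equals the first-order
recursion, and for any Z it equals correlating the residuals of
rank-regressions on Z (both identities are tested to 1e-10—1e-12). Partial
p-values use n − |Z| − 2 df. Event–regulator correlations are BH-adjusted
within each study. The zero-order vs partial comparison contrasts the
absolute coefficients of all event pairs by the rank-sum test, BH-adjusted
across the covariate sets tested, reporting median |ρ| before/after and the
median shift. LOESS smoothing is tricube-weighted local linear regression
without robustness iterations (statsmodels lowess, `it=0`), for descriptive
developmental trajectories; span must cover at least 3 points.

## Synthetic cohorts

The generator emulates three designs: a developmental cohort (prenatal
56–260 vs postnatal 280–~14 900 days post-conception, birth at 266 days —
standard gestation, used as the prenatal/postnatal boundary), a DM1 cohort
(adult patients vs unaffected adults, ages 23–70 years), and a healthy-adult
cohort. Ages are log10-uniform within each range.

**Regulator trajectories.** Each regulator follows a logistic curve in
log10(age) with midpoint at birth and steepness 6 per log10 unit, anchored
at typical adult cortex log2-CPM plateaus (CELF1 5.5, MBNL1 6.0, MBNL2 7.0),
plus Gaussian donor noise (sd 0.3, log2 scale). The curve span is calibrated
by quadrature over the cohort age design so the postnatal-minus-prenatal
group mean difference equals the configured developmental log2 fold changes
(defaults CELF1 −1.23, MBNL1 +1.60, MBNL2 +2.66) in expectation — a raw
span equal to the logFC would undershoot because neither group sits fully on
its plateau.

**Balance coupling.** The per-sample splicing-activity balance is the
composite MBNL1 + MBNL2 − CELF1, standardized against the noise-free
developmental design so the scale is identical across cohort kinds. A
regulated event's inclusion is
Ψ = logit⁻¹(baseline + sign·sensitivity·z + ε), ε ~ N(0, 0.2); baseline and
sensitivity are solved per event so that the design-average prenatal and
postnatal balances hit target inclusions whose difference |ΔΨ| is drawn
uniformly from [0.3, 0.8]. 25% of regulated events have higher prenatal
inclusion (sign −1), matching the roughly 1:3 fetal-up:fetal-down ratio seen
in cortex atlases. Unregulated events (90% by default) have constant
logit-baselines drawn from Ψ ∈ [0.05, 0.95].

**DM1 shift.** Disease shifts each DM1 sample's *activity* balance toward
its fetal reference by the fraction `dm1_shift` (default 0.6) of the
adult→fetal span, on the logit scale — `dm1_shift = 1` reproduces the
prenatal mean exactly. The mild DM1 mRNA changes (defaults MBNL1 +0.50,
MBNL2 +0.44, CELF1 −0.09, log2, DM1 − unaffected) are layered onto the
*measured* expression afterwards and deliberately do not feed back into
activity: sequestered protein is not rescued by extra mRNA. This is what
makes the generated data reproduce the key observational signature —
pairwise event correlations in the DM1 cohort collapse when controlling for
disease state but not when controlling for measured regulator expression,
while in the developmental cohort controlling for age or regulator
expression collapses them.

**Counts.** Per event and sample, total reads ~ Poisson(depth, default 50)
and inclusion ~ beta-binomial(total, Ψ, concentration 30) — the simplest
overdispersed model for junction counts; concentration → ∞ recovers the
binomial. All randomness flows from one seed through named substreams
(truth/ages/regulators/psi-noise/counts), so cohorts are bitwise
reproducible; paired designs share one truth table across cohorts.

**What the generator does not emulate.** No read-level artifacts (mappability,
positional bias, 3′ coverage decay), no isoform complexity beyond binary
inclusion/skipping, no batch or library-prep effects, no correlated nulls,
and regulator→event coupling is monotone through a single composite.
Passing tests therefore demonstrate correctness and calibration of the
statistics under the stated model, not robustness to every artifact of real
RNA-seq.

## Numerical and operating characteristics

Default study conditions for validation: 2000 events, 10% regulated,
20 samples per group, depth 50, concentration 30. Under these conditions
(seeded, asserted in tests): the detection rule recovers ≥ 80% of regulated
events (in practice ~100%), the shuffling FDR estimate stays below 5%
(~0.2–2% across seeds), the rank-sum type-I error at α = 0.01 is within
Monte-Carlo error at 10 000 replicates, and the partial-correlation collapse
patterns above hold. Problem sizes in tests and examples (150–2000 events,
20–40 samples, 20–100 shuffles) keep the full validation suite under a
minute while leaving all statistical assertions well-powered.

## Known limitations

- The PSI estimator ignores read-position information within exons; credible
  intervals are not reported (the posterior is available if needed).
- TMM assumes most genes are not differentially expressed between samples;
  with few genes (< ~100) the trimmed estimate is noisy.
- The permutation FDR shuffles labels unstratified; stratified designs
  (by dataset or subregion) would need a custom shuffle.
- Partial Spearman p-values rely on the t-approximation, which is liberal at
  very small n with many covariates.
- Hierarchical clustering of correlation heatmaps is presentation-only and
  not implemented.
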