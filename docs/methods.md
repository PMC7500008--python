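# Methods

This note documents the statistical model behind `mirsig`, the parameter
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions used throughout.

## Setting

The unit of analysis is a miRNA × sample matrix of raw read counts from a
two-cohort design: tumors without (N0) and with (N1) regional lymph-node
metastases. Counts must be integers — the testing machinery models counts,
not normalized expression — and each sample carries a node-status label and
optionally a Gleason score in [6, 10]. Sample order everywhere downstream
is canonicalized to the count-matrix column order; a count column without
an annotation is fatal, while surplus annotation rows are dropped with a
warning (the matrix defines the analysis set). Read-level processing
(FASTQ, adapter trimming, miRNA database mapping) is out of scope: the
pipeline starts from a finished count table.

## Normalization

Counts per million with a between-sample factor:

    CPM[m, s] = counts[m, s] / lib_size[s] * 1e6 / factor[s]

with `lib_size` the column sum. Four factor methods are provided:

- **TMM** (default). For each sample against a reference, log2 ratios
  M and average abundances A are computed over miRNAs positive in both;
  the top/bottom 30% by M and 5% by A (by mid-rank) are trimmed; the
  remaining M values are averaged with inverse asymptotic-variance weights
  `(N−x)/(Nx) + (N_r−x_r)/(N_r x_r)`; the factor is 2 to that mean. The
  reference is the sample whose 75th percentile of counts/library-size is
  closest to the across-sample mean of that quantity. These are the
  de-facto standard trim fractions and weights for this method; no
  parameter here is fitted to data.
- **RLE**: per-sample median of count / per-miRNA geometric mean over rows
  positive in every sample, divided by library size.
- **UQ**: the 0.75 quantile of the sample's nonzero counts over its
  library size.
- **TC**: all factors 1 (library size alone).

TMM/RLE/UQ factor vectors are rescaled to geometric mean 1 so CPMs are
comparable across methods; TC is the identity by definition. A concordance
diagnostic reports, for every method pair, the Spearman correlation of
vectorized log2(CPM + 0.5) matrices and the largest per-sample |log2 factor
ratio|; under composition bias (a subset of miRNAs inflated in one cohort)
the TC row diverges from the robust methods, which is the intended use of
the diagnostic. The pseudocount 0.5 avoids log 0 and is standard.

Expression filtering retains a miRNA if its CPM reaches `min_cpm` (default
1.0) in at least `ceil(min_fraction × n_samples)` samples (default 50%).
These thresholds are a convention of this package — sensible for ~10⁶-read
miRNA libraries — and are fully configurable; there is no canonical value.

A note on exactness: TMM is only *approximately* invariant to rescaling a
single library. Its M values are scale-free, but the precision weights
depend on absolute counts, so rescaling one library shifts the trimmed
weighted mean by a few tenths of a percent. RLE and UQ are exactly
invariant (after the geometric-mean-1 rescaling).

## Differential expression

Each filtered miRNA is tested twice, and significance requires both routes
to agree — an intersection rule that trades a little power for robustness
to either model being wrong:

1. **Mann–Whitney U** on CPM (rank tests are invariant to monotone
   transforms, so CPM vs log-CPM is immaterial). U counts pairs with
   x > y plus half the ties. In `auto` mode the p-value is exact — from
   the tie-free rank-sum null distribution computed by dynamic
   programming — whenever n₁+n₂ ≤ 16 and the pooled sample has no ties,
   and otherwise uses the normal approximation with tie-corrected variance
   and a 0.5 continuity correction. Forcing `exact` with ties enumerates
   all labelings of the pooled multiset. Two-sided p is 2·min(lower tail,
   upper tail), capped at 1 and clamped above 0.

2. **NB quasi-likelihood F-test (QLF)** on raw counts. Per miRNA a
   negative-binomial log-linear model (intercept + N1 indicator, offset =
   log(lib_size × factor)) is fitted by IRLS at a fixed dispersion.
   Dispersions come from a method-of-moments estimator: counts are scaled
   to a common effective depth, within-cohort residual variance is solved
   for φ in Var = c·μ + φμ² (floored at 10⁻⁶), the common dispersion is
   the across-miRNA median, and tagwise values interpolate between raw and
   common on the log scale with weight min(1, 20/df_resid) on the common
   component. The quasi-dispersion is residual deviance / df, shrunk
   toward its across-miRNA mean with prior df 10; the statistic
   F = (null deviance − full deviance) / quasi-dispersion is referred to
   F(1, df_resid + prior df). IRLS failures (50 iterations) flag the
   record with p = 1 rather than raising. This is a deliberately simple,
   documented quasi-likelihood test validated by simulation (null type-I
   error ≈ 0.04 at nominal 0.05 in the packaged null study); it does not
   attempt numerical equivalence with any external implementation's
   dispersion machinery.

The fold change is log2((mean CPM in N1 + 0.5) / (mean CPM in N0 + 0.5)) —
a ratio of group means with a pseudocount, not the GLM coefficient, which
is exported separately as a diagnostic (their signs agree except at
near-zero effects). Both p-value families are Benjamini–Hochberg adjusted
across all tested miRNAs. The consensus call is:

    N1-miR  iff  FDR_MW < α  and  FDR_QLF < α  and  log2FC ≥ log2(1.5)
    N0-miR  symmetric with log2FC ≤ −log2(1.5)

with α = 0.05 and the 1.5-fold threshold *inclusive*. Because the call set
is an intersection, it is contained in each single-test call set — a
structural guarantee asserted in the test suite.

**High/low relative-expression frequencies.** For each miRNA, a sample is
flagged *high* if its CPM exceeds 1.5× the across-all-samples arithmetic
mean (including the sample itself) and *low* below mean/1.5. Cohort
frequency differences are tested with two-sided Fisher exact tests on the
high-vs-not and low-vs-not 2×2 tables; each family is BH-adjusted across
miRNAs and the smaller adjusted value is reported. The choice of Fisher +
BH here is this package's interpretation of "comparing frequencies between
cohorts"; all-zero rows are skipped with a warning.

## Signature analysis

Centered log expression `l[m,s] = log2(CPM+0.5) − row mean` makes every
miRNA's row mean zero, so a sample's value is its log2 deviation from the
cohort-wide geometric-mean reference — the only reference that turns the
G0/G1 split into a pure sign rule. The per-sample score is

    Δ avg. log2 FC[s] = mean over N1-miRs of l[·,s] − mean over N0-miRs of l[·,s]

Scores < 0 define G0, > 0 define G1; an exact zero follows a configurable
tie policy (default G0, logged — strict inequalities leave ties undefined,
and at float resolution they essentially never occur). Enrichment of G1 in
the N1 cohort is tested with the two-sided Fisher exact test
(point-probability rule with a 1+10⁻⁷ tolerance factor, the classical
definition) on the G×N table. Swapping the two module roles negates every
score, transposes the G rows and leaves the Fisher p unchanged.

Module structure: pairwise Spearman correlations (mid-rank ties, p from
the t approximation with n−2 df — adequate in the n ≈ 44 regime; exact
permutation p would add nothing at this n) across samples for all module
members, averaged over unordered within-module pairs and over all cross
pairs; constant rows are dropped with a warning. Phenotype correlations
report each miRNA's Spearman r against the 0/1 node feature and, where at
least three samples carry one, against Gleason score, together with the
Gleason-vs-node correlation itself. The module sets default to the
consensus calls but can be supplied explicitly (e.g. a published 18-miRNA
signature); note that published set listings sometimes leave the arm of a
miRNA (-5p/-3p) ambiguous, so explicit sets are taken verbatim.

## Synthetic data

The generator draws, from a single seed:

- library sizes L_s ~ log-normal(log 2×10⁶, 0.3) — realistic miRNA-seq
  depth variation;
- baseline relative abundances p_m ~ log-normal(0, 1.5), renormalized to
  sum 1 — the σ = 1.5 skew is this package's choice for the heavy-tailed
  abundance distribution typical of miRNA libraries;
- a latent factor z_s = β·1[s ∈ N1] + Normal(0, latent_sd), with β = 1
  (log2 units) and latent_sd = 0.5 by default;
- means μ[m,s] = L_s · p_m · 2^(δ_m z_s), where δ = +1 for the 9 up-module
  miRNAs, −1 for the 9 down-module miRNAs, 0 otherwise;
- counts ~ NB(μ, φ) with Var = μ + φμ², φ = 0.3 by default (φ = 0 is
  Poisson); optional composition bias multiplies a chosen fraction of null
  miRNAs by a chosen fold in N1 samples only.

Default design: 24 N0 + 20 N1 samples, 300 miRNAs. Driving both modules
with one shared latent factor (rather than independent group shifts) is
what produces within-cohort positive correlations inside each module and
negative correlations across modules — the structure the signature
analysis is designed to detect; independent shifts would leave miRNAs
conditionally independent given the cohort.

What the generator does *not* emulate: isomiR structure and sequence
content, count-dependent dispersion trends, batch effects, zero inflation,
and correlated clinical covariates (no Gleason scores are simulated).
Recovery results on this generator therefore speak to the statistical
contract of the pipeline — calibration, recovery of planted
latent-factor modules, robustness of normalization to composition bias —
not to any specific biological dataset.

### Power at the default design

At the default conditions the planted effect is near the detection limit:
per-sample log2 noise is ≈ √(0.3/ln²2 + 0.5²) ≈ 0.93 against an effect of
1.0, and BH across 300 miRNAs pushes the effective per-test threshold to
p ≈ 0.002. An oracle Welch t-test on log2 CPM attains mean sensitivity
≈ 0.56 over seeds here, and the dual-test consensus caller ≈ 0.45–0.50
with observed FDR ≈ 0.03 — the intersection rule deliberately gives up a
little sensitivity for near-zero false calls. Sensitivity is not a fixed
property of the pipeline but of this design point; at larger effects or
lower dispersion the caller recovers essentially everything (see the
planted 4-fold test in the suite). The signature layer is much less
power-limited: averaging 9 + 9 miRNAs defeats the per-miRNA noise, so the
G×N Fisher test rejects in ~100% of replicates at β = 1 while staying at
the nominal ~5% under β = 0.

## Numerical conventions and edge cases

- All reported p-values lie in (0, 1]; BH output likewise.
- Factors must be strictly positive and finite; zero-total libraries are
  rejected outright.
- TMM with identical composition (max |M| < 10⁻⁶) short-circuits to 1,
  avoiding trimming noise on degenerate inputs.
- Dispersion floor 10⁻⁶; quasi-dispersion floor 10⁻¹⁰; deviance
  differences below 10⁻¹⁰ are treated as exactly zero so that a no-signal
  model yields F = 0, p = 1.
- Constant vectors make Spearman r undefined and raise a dedicated error
  (rows are dropped with a warning inside the correlation-structure
  aggregation).
- Fisher tables must be non-negative with a positive total.
- Result TSVs serialize floats with 6 significant digits and round-trip
  at that precision; count-matrix round trips are exact.

## Problem sizes in the packaged studies

The simulation studies shipped with the package use: 20 replicates of
1000 null miRNAs × 20 samples for QLF calibration; 50 replicates at the
default design (300 × 44) for recovery, module correlations and
enrichment; 100 replicates for the null enrichment rate; 200/500/200
random instances for the Mann–Whitney/Fisher/BH enumeration-oracle
comparisons; 50 random matrices for the normalization oracles. These sizes
give standard errors comfortably inside the asserted bands while keeping
the full suite fast on a single CPU.
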