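# Methods

## Model and estimand

All three outcome types share one additive genetic model on standardized
genotypes.  For a continuous trait,

    Y_i = mu + sum_{j=1}^{p} X_ij u_j + e_i,    e_i ~ N(0, sigma_e^2),

where X_ij is the allele count of causal SNP j in individual i, centered
and scaled to unit variance, and the u_j are fixed (not random) effects.
Writing sigma_g^2 = sum_j u_j^2 under working independence of the causal
genotypes, the narrow-sense heritability is h^2 = sigma_g^2 / sigma_Y^2 =
1 - sigma_e^2 / sigma_Y^2.  The package estimates the pair (sigma_Y^2,
sigma_e^2) rather than (sigma_g^2, sigma_e^2): the total variance has a
trivial stable estimator, whereas sigma_g^2 would inherit the noise of
thousands of coefficient estimates.

Dichotomous traits replace Y with D in {0,1} under a linear working model;
sigma_D^2 = Dbar(1 - Dbar) is the total variance and the observed-scale
estimate h_o^2 = 1 - sigma_eps^2 / sigma_D^2 is mapped to the liability
scale (below).  Age-at-onset traits use the log-normal accelerated failure
time model Y0 = log T with normal errors; right censoring is handled by
inverse-probability-of-censoring weighting (IPCW), so the same linear
machinery applies with observation weights.

## Pipeline

**Standardization** uses the per-SNP sample mean and sample SD (ddof = 1),
not the binomial 2q(1-q): it makes the unit-variance property exact in
sample, which every downstream scale convention relies on.  Missing calls
are mean-imputed per SNP on load (their standardized value is then 0);
monomorphic SNPs, including constant all-heterozygote columns, are dropped.

**Screening (Step 1)** reduces M below the sample size.

* SIS ranks SNPs by |(weighted) marginal correlation| with the outcome and
  keeps the top `keep_fraction` (default 0.3).  Adequate up to roughly
  10,000 SNPs.
* ITRRS repeatedly fits ridge regression on the retained SNPs of each
  chromosome and keeps the top `keep_fraction` (default 0.5) by
  |coefficient|, for `n_iterations` rounds; per-chromosome survivors are
  combined.  The joint fit respects LD, making ITRRS the right screener
  for large panels.  The ridge objective is
  sum_i w_i (y_i - a - x_i b)^2 + lambda * N * ||b||^2 with the intercept
  unpenalized, solved in primal or dual form depending on the column
  count, so one `shrinkage` value (default 0.01) means the same thing at
  any sample size.  The iteration count should be chosen so the survivor
  budget stays well above the plausible number of causal SNPs: the test
  suite's five-chromosome runs (M = 3000) use 2 iterations at keep 0.5
  (750 survivors), matching the survivor budget the full-scale procedure
  (5-6 iterations on hundreds of thousands of SNPs) ends with.
* Ties in either ranking break toward the lower SNP index, so screening is
  deterministic with no seed.

**Refitted cross-validation (Steps 2-4).**  The sample is split into
halves of sizes ceil(N/2) and floor(N/2) (deterministic given
`split_seed`).  On one half a lasso with `cv_folds`-fold (default 10)
cross-validation selects a support; on the other half an OLS refit of the
outcome on that support yields the residual-variance estimate; roles are
swapped and the two estimates averaged.  The refit denominator is
n - |support| - 1; with observation weights it is the exact weighted
effective degrees of freedom V1 - tr((Z'WZ)^{-1} Z'W^2 Z), which reduces
to n - |support| - 1 at unit weights and to (V1^2 - V2)/V1 at empty
support (V1 = sum w_i, V2 = sum w_i^2).  This trace form matters: with
heavy IPCW weights the naive count understates the degrees of freedom
consumed and biases sigma_e^2 downward by tens of percent.  An empty
support is a legitimate selection and degenerates to the (weighted)
sample variance, keeping the estimator defined under h^2 = 0.

**Penalty rule.**  `penalty_rule="min"` (default) takes the penalty
minimizing the mean cross-validated error; `"one_se"` takes the most
regularized model within one standard error of that minimum.  The one-SE
rule is attractive when the loss itself is noisy (estimated censoring
weights, bootstrap weights), but at moderate sample sizes under IPCW
weighting the fold-level error is noisy enough that the *null model*
frequently falls within one SE of the minimum; the selection then collapses
to the empty support, sigma_e^2 inflates to sigma_Y^2, and h^2 is driven
toward zero.  For that reason the point estimate uses the min rule for all
outcomes, while the one-SE rule remains the calibration rule inside the
bootstrap, where conservatism costs only a slightly larger SE.  A support
cap (`max_support`, default half-sample minus 2) keeps the opposite-half
refit full rank.

**Covariates** (known risk factors) are exempt from screening and
selection: screeners and the lasso see the outcome residualized on W,
each refit regresses the raw outcome on [selected SNPs, W] jointly, and
the reported heritability removes the covariate component:
h^2 = 1 - {sigma_e^2 + beta' var(W) beta} / sigma_Y^2, with the
beta' var(W) beta term averaged over the two refits.  Note the estimand
keeps total phenotypic variance (including covariate-attributable
variance) in the denominator.

## Liability scale

For a 0/1 trait with population prevalence K, z denotes the standard
normal density at the quantile truncating the upper K tail.  Without
ascertainment, h_l^2 = h_o^2 K(1-K)/z^2 (Robertson transform).  Under
case-control oversampling with sample case fraction P,
h_l^2 = h_o^2 K^2 (1-K)^2 / {P(1-P) z^2}; the two branches coincide at
P = K.  K is required user input (disease prevalence is external
knowledge); P defaults to the sample case fraction.  With h_o^2 = 0.244,
K = 0.004 and P = 4312/8668 this gives 0.110 — the package's reference
worked example.

## IPCW conventions

The censoring survival function Sc is the Kaplan–Meier product-limit
estimator with the roles of events and censorings exchanged.  Two
conventions are fixed deliberately:

* **Left-limit evaluation**: weights use Sc(Y_i-), so an event at time t
  draws only on censoring information strictly before t.
* **Event-first ties**: an event tied with a censoring at the same time
  leaves the risk set before the censoring is counted.

Weights are W_i = delta_i / Sc(Y_i-); censored subjects get exactly zero.
The weighted outcome variance is V1 * sum W_i (Y_i - Ybar_w)^2 /
(V1^2 - V2).  The denominator is pinned down by the unit-weight limit:
V1^2 - V2 = n(n-1) recovers the ordinary unbiased sample variance, and the
n-1-consistency fails for the alternative (V2 - V1), which vanishes at
unit weights.  Consistency of the whole survival path requires the
censoring support to cover the failure-time support and censoring to be
independent of genotype; a covariate-dependent censoring model is out of
scope.  With zero censoring every weight is 1 and the survival path
reproduces the continuous path exactly (all-ones weight vectors are
canonicalized to the unweighted code path).

## Weighted bootstrap

Standard errors perturb each observation with i.i.d. positive weights of
mean 1 and variance 1 — standard exponential draws, a Bayesian-bootstrap
style scheme (the weight law is this package's choice; any mean-1,
variance-1 positive law fits the theory).  Two phases:

1. **Calibration**: over `n_calibration` (default 100) weighted datasets,
   the one-SE CV penalty is computed in the Step-2 context (first half of
   the fixed split) and averaged on the natural scale.  Weight noise pushes
   this average above the unweighted choice.
2. **SE**: `n_replicates` (default 100) fresh weighted datasets re-run
   Steps 2–4 with the penalty fixed at the calibrated value; the SE is the
   standard deviation of the replicate estimates.  For survival outcomes
   the censoring Kaplan–Meier is itself re-estimated under the replicate
   weights; for binary outcomes the weighted case fraction enters both
   sigma_D^2 and the ascertainment correction.

Screening is *not* re-run inside the bootstrap: the residual-variance
estimator's insensitivity to the screened set (its oracle property) makes
the perturbation unnecessary, and skipping it is the dominant cost saving.
The sample split is also held fixed across replicates so that weight noise
is the only source of replicate variability — degenerate (all-ones)
weights therefore give SE = 0 exactly.

## Synthetic-data generator

The generator emulates resampling from a pool of real phased haplotypes.
Each pool haplotype is a first-order binary Markov chain along the
chromosome with adjacent-allele correlation `ld_decay` (so correlation
decays as ld_decay^d with distance d; realized adjacent-SNP genotype r^2
is about ld_decay^2).  Per-SNP allele frequencies follow a slowly varying
reflected random walk inside `maf_range` (default 0.05–0.5, step SD 0.02)
— tightly linked SNPs in real LD blocks share allele frequencies, and
near-equal adjacent frequencies let the chain reach the nominal
correlation without truncating transition probabilities.  2N haplotypes
are drawn from the pool (default size 2000) with replacement and paired,
adding the bounded haplotype diversity of pool resampling.  Chromosomes
are independent.

Causal SNPs are drawn uniformly (optionally restricted to MAF <= theta),
with effects u_j ~ N(0, sigma_g^2/p), sigma_g^2 = h^2 sigma_e^2/(1-h^2)
(so sigma_g^2 = 1/9 at h^2 = 0.1 and 1.5 at h^2 = 0.6 with sigma_e^2 = 1);
`exact_normalization` rescales so sum u_j^2 = sigma_g^2 exactly, used by
tests that need exact truth.  Outcomes: continuous Y = mu + Xu + e (mu = 0
by default); binary D = 1{Y > t_K} with t_K the theoretical upper-K
quantile of N(mu, sigma_Y^2), keeping replicates independent of each
other's empirical quantiles; survival treats Y as log failure time with
N(0, censor_sd^2) censoring — censor_sd = 2 yields ~50% censoring at the
default trait scale.  The untyped-causal scenario removes each causal SNP
and `flank_exclusion` (default 5) neighbors per side, clipped at
chromosome boundaries, leaving only LD proxies observable.

What the generator does *not* emulate: recombination-map block mosaics
(LD decays geometrically rather than in discrete blocks), population
structure and relatedness, genotyping error, and realistic MAF spectra
(no rare-variant tail below `maf_range`).  Passing recovery tests
therefore demonstrate the estimator's behaviour under clean polygenic
architecture with local LD — not robustness to stratification or
differential genotyping quality.

## Numerical choices

* Lasso CV path: 50 penalties spanning two decades below the data-derived
  maximum (eps = 0.01); coordinate-descent tolerance 1e-3 on standardized
  columns (selection and refit variance move by < 1e-3 versus 1e-4 while
  fits run ~3x faster); max 2000 iterations.
* A fixed penalty of exactly 0 falls back to dense least squares (used by
  the OLS-oracle equivalence test).
* CV folds are shuffled deterministically from `split_seed`-derived seeds;
  the two half-sample selections use distinct derived fold seeds.
* All ranking ties break toward the lower SNP index; bootstrap sub-seeds
  derive from `numpy.random.SeedSequence` and stay below 2^31.
* Degenerate inputs raise typed errors: constant SNP columns
  (DegenerateSNPError), zero-variance outcomes, all-censored samples, and
  weight patterns with V1^2 <= V2.

## Study sizes used by the test suite

The full-scale experiments behind this method run at N up to 20,000 and
M up to 250,000; the package's checks use desk-scale analogues chosen to
preserve the governing ratios (survivor budget versus p, half-sample size
versus support): continuous recovery and the asymptotic-variance check at
N = 2000, M = 300–1000; the age-at-onset design at N = 3000, M = 3000
over five pseudo-chromosomes with p = 100 and 50% censoring (30
replicates per heritability level); the untyped-causal scenario at
N = 5000, M = 2000, p = 60 in the high-LD regime (ld_decay 0.97, proxy
r^2 ≈ 0.8 at the nearest observable SNP); the binary liability check at
N = 3000, M = 1000, K = 0.5.  The asymptotic-variance check verifies that
the empirical variance of the estimate over 200 replicates sits within a
factor 2 of 4 h^2 (1-h^2)^2 / N.

## Known limitations

* At desk-scale N with weak per-SNP signal (h^2 = 0.1 spread over 100
  causal SNPs, 50% censoring), selection misses part of the genetic
  variance and the estimate is biased toward zero by up to ~0.05; the
  bias shrinks with N, as the full-scale experiments show.
* IPCW weights grow as events approach the censoring support boundary,
  inflating the variance of both sigma_e^2 and sigma_Y0^2; the AFT path
  needs large samples by construction.
* One random split is used by default; split-to-split variability is part
  of the estimator's noise (the bootstrap holds the split fixed and so
  reports weight-perturbation variability only).
* The ascertainment-corrected liability transform is accurate for small
  h_o^2; for highly heritable, highly ascertained traits a full
  liability-model correction would be needed.
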