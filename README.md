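# herra

Narrow-sense heritability estimation from GWAS genotype data by
regularized regression, for continuous, dichotomous and right-censored
age-at-onset outcomes.

## The problem

Mixed-model (GREML-type) heritability estimators approximate the genetic
similarity between individuals from *all* genotyped SNPs.  When the causal
fraction is small this masks the signal and inflates the variance of the
estimate, and when causal SNPs are not genotyped at all the estimate can be
badly biased downward.  And no random-effects estimator handles age-at-onset
cohorts, where disease-free subjects are right-censored rather than
unaffected.

HERRA takes the fixed-effects route instead.  Under the additive model

    Y_i = mu + sum_j X_ij u_j + e_i,        e_i ~ N(0, sigma_e^2),

with standardized genotypes X_ij, the heritability is

    h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) = 1 - sigma_e^2 / sigma_Y^2.

sigma_Y^2 has a trivial unbiased estimator, so the whole difficulty moves
into sigma_e^2, which is estimated by refitted cross-validation:

1. **Screen** the M SNPs below the sample size — marginal correlation
   ranking (SIS) for moderate panels, or per-chromosome iteratively
   thresholded ridge regression (ITRRS) for large ones.
2. **Split** the sample into halves; run a 10-fold cross-validated lasso on
   one half to select a sparse SNP set.
3. **Refit** by ordinary least squares on the *other* half using only the
   selected SNPs; its residual variance is nearly unbiased for sigma_e^2
   because that half played no role in selection.  Swap the halves.
4. **Average** the two estimates and form h^2 = 1 - sigma_e^2 / sigma_Y^2.

Binary traits use the same machinery on the 0/1 outcome with
sigma_D^2 = Dbar(1-Dbar) and are mapped to the liability scale by the
Robertson transform, with an ascertainment correction
`h_o^2 K^2(1-K)^2 / {P(1-P) z^2}` for case-control sampling (population
prevalence K, sample case fraction P).  Age-at-onset outcomes use a
log-normal AFT model with inverse-probability-of-censoring weights
W_i = delta_i / Sc(Y_i-) from the Kaplan–Meier estimate of the censoring
distribution; all regression steps and the outcome variance are weighted
accordingly.  Standard errors come from a weighted (exponential-weight)
bootstrap that re-runs Steps 2–4 with a penalty calibrated on a first batch
of weighted datasets.

Intended users: statistical geneticists who have PLINK-format GWAS data and
want a heritability estimate that is robust to sparse, possibly untagged
causal architecture — including, uniquely, for survival phenotypes.

## Worked example

Simulate a 2000-sample, 1000-SNP panel with 30 causal SNPs and h² = 0.3,
then estimate with SIS screening and a 50-replicate bootstrap SE:

```sh
herra simulate --out toy --n-samples 2000 --n-snps 1000 \
      --n-causal 30 --h2 0.3 --seed 7
herra estimate --bfile toy --pheno toy.pheno.tsv --outcome continuous \
      --screen sis --keep-frac 0.3 --bootstrap 50 --calibrate 20 \
      --seed 11 --out toy_result
```

`toy_result.json` contains (abridged):

```
h2_observed    0.2506
sigma_e        0.9743
sigma_total    1.3000
se             0.0242
n_screened     300
support_sizes  [106, 89]
```

Reading: screening kept 300 of 1000 SNPs; the two half-sample lasso
selections picked 106 and 89 SNPs; the opposite-half refits averaged to
sigma_e^2 = 0.974 (truth 1.0), and with the sample outcome variance 1.300
the estimate is h² = 1 − 0.974/1.300 = 0.251 ± 0.024.  For this particular
replicate the realized genetic variance gives a true h² of 0.258, so the
estimate is within one standard error.  For binary traits add
`--prevalence K` to obtain the liability-scale estimate; for survival
phenotypes pass `--outcome survival` with `time`/`status` columns.

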