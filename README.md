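# adipomr

A Mendelian-randomisation (MR) toolkit for testing the causal effect of
adiposity (BMI, waist-hip ratio) on binary depression outcomes, written for
genetic epidemiologists who need both summary-statistic and individual-level
MR in one pipeline.

MR uses genetic variants as instrumental variables for a modifiable exposure
X. For variant *j* with SNP-exposure effect β̂_Xj (SE σ_Xj) and SNP-outcome
log-odds effect β̂_Yj (SE σ_Yj), the per-variant Wald ratio is
θ̂_j = β̂_Yj / β̂_Xj with first-order SE σ_Yj / |β̂_Xj|. The package implements:

- **Two-sample MR** over harmonised GWAS summary statistics:
  inverse-variance weighting θ̂_IVW = Σ w_j θ̂_j / Σ w_j with w_j = 1/σ_j²
  (fixed-effects, and multiplicative random-effects scaled by
  √max(1, Q/(k−1))); MR-Egger weighted regression with a free intercept
  estimating average directional pleiotropy; the weighted median (consistent
  when ≥ 50% of the weight is from valid instruments) and the penalised
  weighted median, which down-weights variant *j* by min(1, 20·p_j) where
  p_j is the χ²₁ upper-tail probability of its heterogeneity contribution
  Q_j = w_j(θ̂_j − θ̂_WM)². Diagnostics: Cochran's Q, I² = max(0, (Q−df)/Q)·100,
  and the median instrument F = median (β̂_Xj/σ_Xj)².
- **Harmonisation**: alignment of both datasets to a shared effect allele
  (sign/frequency flips for swapped alleles, exclusion of irreconcilable
  pairs), plus the standard sensitivity filters — an open MAF window around
  0.5, discordant trait-raising-allele removal against a second ancestry's
  estimates, and named-variant removal.
- **One-sample MR** on individual-level data: rank-based inverse-normal
  transformation of the trait, sex-specific trait-raising-allele coding from
  joint multivariate regressions, genetic-risk-score weights cross-fitted
  over K = 100 random leave-out blocks (no phenotype informs its own
  weights), then two-stage predictor-substitution IV estimation of the
  log-odds per 1-SD exposure within sex-by-region strata, pooled by
  fixed-effects meta-analysis (β_pool = Σβ_i/σ_i² / Σ1/σ_i²) with I², and
  subgroup contrasts via Fisher's z = (β₁−β₂)/√(σ₁²+σ₂²).
- **Non-linear MR** by the control-function method: the stage-1 residual
  enters a logistic model of the outcome on exposure and exposure², and the
  quadratic Wald test is the non-linearity test.
- **Observational contrasts**: adjusted logistic ORs per 1-SD exposure and
  per BMI category (normal / overweight / obese; underweight excluded).
- A **synthetic cohort generator** producing genotype dosages, a polygenic
  confounded exposure, region-structured binary outcomes with optional
  pleiotropy and quadratic effects, and CIDI-style depression items, so the
  whole pipeline is testable without restricted cohort data.

## Worked example

Simulate a two-sample summary-statistic pair with a true causal odds ratio of
0.81 per 1-SD exposure, harmonise, filter, and run all four estimators:

```python
import numpy as np
from adipomr import (SimConfig, simulate_sumstats_pair, align_effect_alleles,
                     apply_exclusion_filters, run_all_estimators, median_f_statistic)

cfg = SimConfig(
    n_individuals=50_000, n_variants=50,
    variant_effects_exposure=np.full(50, 0.08),
    causal_effect_linear=np.log(0.81),
    seed=7,
)
pair = simulate_sumstats_pair(cfg)
hset = align_effect_alleles(pair.exposure_stats, pair.outcome_stats)
hset, counts = apply_exclusion_filters(hset, {"maf_window": (0.45, 0.55)})
print("removed:", counts, "retained:", hset.n_retained)
print("median F:", round(median_f_statistic(pair.exposure_stats).median_f, 2))
res = run_all_estimators(hset, n_boot=1000, seed=7)
print(res[["method", "n_snps", "OR", "ci_low", "ci_high", "pval"]].round(3).to_string(index=False))
```

prints

```
removed: {'maf_window': 7} retained: 43
median F: 115.88
    method  n_snps    OR  ci_low  ci_high  pval
 IVW_fixed      43 0.716   0.614    0.835 0.000
IVW_random      43 0.716   0.614    0.835 0.000
     Egger      43 0.616   0.081    4.660 0.639
        WM      43 0.714   0.573    0.889 0.003
       PWM      43 0.713   0.543    0.935 0.015
```

Seven variants whose outcome-side MAF falls strictly inside (0.45, 0.55) are
excluded as harmonisation-ambiguity risks. All four estimators recover an OR
near the simulated 0.81 (IVW 0.72 [0.61, 0.84] — within sampling error of
truth at this sample size); the MR-Egger CI is wide, as expected when the
per-variant exposure effects span a narrow range, and its intercept is
compatible with zero (no directional pleiotropy was simulated).

The same pipeline is scriptable from the shell:

```sh
adipomr simulate sumstats --seed 7 --out sim/
adipomr harmonise --exposure sim/exposure_sumstats.tsv --outcome sim/outcome_sumstats.tsv --out harm/
adipomr twosample --harmonised harm/harmonised.tsv --seed 7 --out mr.tsv
adipomr report --seed 7 --out full_run/   # full pipeline incl. one-sample MR
```

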