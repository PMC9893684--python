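# Methods

## Generative model

The synthetic cohort emulates a large population biobank with
questionnaire-based depression phenotyping. For individual *i* and variant
*j*:

- Genotype dosages G_ij ~ Binomial(2, maf_j), independent across variants
  (no linkage disequilibrium). Downstream code accepts fractional dosages in
  [0, 2], so imputed data are a drop-in replacement; the generator's hard
  calls are the simplest special case.
- Exposure X_i = Σ_j γ_j G_ij + a·U_i + ε_i with U_i ~ N(0,1) a single shared
  confounder, ε_i ~ N(0, σ²) (σ = 1 by default), and per-allele effects γ_j
  in exposure-SD units (optionally sex-specific, which exercises the
  sex-resolution rule in allele coding).
- Outcome: logit P(Y_i = 1) = β₀ + r_{region(i)} + θ·X̃_i + θ₂·X̃_i² +
  Σ_j δ_j G_ij + b·U_i, where X̃ is the within-sample standardised exposure,
  θ and θ₂ are the linear and quadratic causal effects (log-odds per SD and
  per SD²), and δ_j are direct variant effects (all zero ⇒ valid
  instruments). β₀ defaults to logit(0.035), matching a ~3.5% prevalence of
  depressive symptoms; ten regions (five urban, five rural) with
  configurable intercepts.
- Depression items: cases endorse at least one of four trigger items (drawn
  with marginal rates 0.95/0.44/0.30/0.25, the first forced when a draw
  yields none) and each of seven CIDI-SF symptom items independently at a
  configurable rate (default 0.25, a free parameter — no generative model
  for item marginals is prescribed anywhere, only the derivation rule);
  controls endorse nothing. Case status is therefore exactly re-derivable:
  depressive symptoms ⇔ ≥ 1 trigger item, major depression ⇔ depressive
  symptoms and ≥ 3 of 7 CIDI-SF symptoms.

What the generator deliberately omits: LD between variants, imputation
uncertainty, relatedness/family structure, missingness (injectable but not
generated), and item endorsement among controls. Passing tests therefore
demonstrate the estimators' statistical behaviour under a clean additive
polygenic model with a single normal confounder — not robustness to LD
pruning errors, population stratification beyond supplied PCs, or phenotype
misclassification.

## Two-sample summary statistics

Two independent cohorts are drawn. Sample 1 yields per-variant slopes of the
*standardised* exposure on dosage (simple linear regressions, closed form),
so Wald ratios are directly on the log-odds-per-1-SD scale of θ. Sample 2
yields per-variant logistic log-odds slopes, fitted by a vectorised Newton
scheme solving each variant's 2×2 information system simultaneously across
variants; a unit test pins it to a per-variant maximum-likelihood fit at
1e-8. Marginal logistic effects are mildly attenuated relative to the
conditional model (non-collapsibility); at the default effect sizes the
factor is ≈ 0.98 and is absorbed by the Monte-Carlo tolerances.

## Estimators and numerical choices

- Wald ratio SE uses the first-order delta method (σ_Yj/|β̂_Xj|), which makes
  fixed-effects IVW algebraically identical to the zero-intercept weighted
  regression of outcome on exposure betas with weights 1/σ_Yj² (asserted to
  1e-10). A second-order SE is easy to add but is not the default because the
  regression equivalence is used as an internal consistency oracle.
- Random-effects IVW is multiplicative with the dispersion floored at 1, so
  it never undercuts the fixed-effects SE. Fixed-effects is the headline
  model unless Cochran's Q rejects at 0.05, in which case the random-effects
  row is flagged instead; both are always reported.
- MR-Egger flips (β̂_Xj, β̂_Yj) pairs jointly so all exposure betas are
  positive (required for the intercept to mean average directional
  pleiotropy), and uses the same floored multiplicative dispersion. At least
  3 variants with unequal exposure betas are required.
- Weighted median: ratios sorted, standardised cumulative weight midpoints
  s_j = (Σ_{k≤j} w_k − w_j/2)/Σw, linear interpolation at s = 0.5. SEs are
  seeded parametric-bootstrap SDs (default 1000 draws): each ratio is redrawn
  from N(θ̂_j, σ_j²) with the inverse-variance weights held fixed. The
  penalised variant multiplies w_j by min(1, 20·p_j) — the published penalty
  constant, exposed as a parameter — and the penalty is re-derived inside
  every bootstrap draw.
- All p-values are two-sided normal; 95% CIs use 1.959964.

## Harmonisation

Strand-complement rescue is never attempted: allele pairs that neither match
nor swap are excluded (`allele_mismatch`), and palindromic-SNP risk is
handled solely by the MAF-window filter, whose bounds are strict — a variant
with outcome-side MAF exactly 0.45 or 0.55 is retained. MAF is
min(eaf, 1−eaf) on the *outcome* dataset, the side whose ancestry defines
the window. Every input variant ends either retained or in a machine-readable
exclusion log with exactly one primary reason code, so filter counts can be
reproduced on real inputs.

## GRS construction

The trait is rank-inverse-normal transformed with the Blom offset,
Φ⁻¹((r − 3/8)/(n + 1/4)), ties sharing average ranks (no offset convention is
mandated by the analysis; Blom is the common default). Trait-raising alleles
are determined per sex from a joint (all-variants-simultaneous) regression of
the within-sex RINT trait on dosages; when the sexes disagree the larger
absolute effect decides, and one coded allele is applied to both sexes.
Variants with cohort MAF < 0.01 are excluded before weighting.

Cross-fitting splits the derivation subset into K = 100 blocks (balanced
random assignment, sizes differing by at most 1, seeded). For each block the
within-sex regression of the RINT trait on all coded dosages plus
principal-component covariates (coefficients discarded) is re-solved with
that block removed, implemented by subtracting the block's X'X and X'y
contributions from the full-sample cross-products — algebraically identical
to refitting on the remaining rows, and asserted against an independent OLS
refit at 1e-8 in the honesty tests. Individuals outside the derivation
subset receive the full-derivation-sample weights of their sex; this
fallback is an assumption (nothing pins down how related individuals should
be scored) and is flagged in the weights object's metadata. Scoring is
complete-case; a cross-fitted GRS is identified only up to block- and
sex-level constants under allele recoding, so coding-invariance holds
exactly for shared weight vectors and within strata.

## One-sample IV estimation

Stage 1: OLS of the exposure on the GRS and covariates within a stratum.
Stage 2: logistic regression of the outcome on the stage-1 fitted exposure
and covariates (predictor substitution), with the coefficient rescaled to
log-odds per 1 SD of the exposure, the SD computed once in the full analysis
sample so stratum estimates share a scale. Model-based stage-2 SEs ignore
stage-1 sampling error and therefore run slightly anticonservative; a seeded
nonparametric bootstrap SE is available as an option, and the null-calibration
suite checks the model-based version stays inside the 99% binomial band at
the default instrument strength. Logistic fits use bounded Newton iterations
with convergence and separation guards; degenerate strata (no cases, constant
GRS, separation) raise a typed error and are dropped from meta-analysis with
a log entry rather than silently pooled. Strata below a configurable case
prevalence can be excluded. Fixed-effects inverse-variance pooling with Q,
I² = max(0, (Q−df)/Q)·100, and Fisher-z contrasts for male/female and
urban/rural follow.

## Non-linear MR

The control function is minimal: stage-1 residual entering linearly only (no
residual² or interaction). The exposure is mean-centred within stratum
before squaring to limit collinearity; coefficients and their covariance are
mapped back to the raw scale via the Jacobian [[1, −2m], [0, 1]], so the
quadratic term and its p-value are centring-invariant while the linear term
transforms by the known affine map. The fitted curve β₁x + β₂x² carries
pointwise variance x²V₁₁ + x⁴V₂₂ + 2x³V₁₂ from the model-based coefficient
covariance (the same covariance the Wald test uses), with grid points outside
the observed exposure range flagged as extrapolation. Near-constant stage-1
fitted values set a collinearity flag. Non-linearity is declared by the
quadratic Wald test alone; no spline or stratified (doubly-ranked)
alternatives are implemented.

## Observational contrasts and categories

The conventional BMI bands are printed with rounding gaps (23.9–24,
27.9–28); they are implemented as half-open intervals [18.5, 24), [24, 28),
[28, ∞) so every value is classified while the conventional labels are kept.
Underweight (< 18.5) individuals are always excluded from the binary
category contrasts, and each non-reference category is contrasted against
normal in its own fit. The per-SD OR standardises the exposure by a supplied
(by convention full-sample) SD, making it invariant to affine rescaling.

## Significance conventions

Three tiers are annotated on every result row: none, tentative (p < 0.05),
and corrected — p < 0.025 for two-sample results (two exposure groups) and
p < 0.013 for one-sample results (four exposure-by-residence groups). The
thresholds are configuration values, not hard-coded.

## Problem sizes in the test and acceptance suites

Replicate suites run at the sizes the properties are stated for: null
calibration uses 500 replicates of two n = 20,000 samples (IVW, 20
instruments) and 500 replicates of an n = 20,000 cohort (two-stage, 50
variants, K = 100 cross-fit); Egger intercept recovery uses 200 replicates
(n = 20,000, mean direct effect 0.01); weighted-median robustness uses 100
replicates at n = 50,000 with 30% invalid instruments; non-linearity
recovery and null coverage use 100 replicates each at n = 50,000; the
confounding motif uses 200 replicates at n = 10,000. The non-linear and
confounding suites score the instrument with the generator's true per-variant
effects — the cross-fit machinery is exercised and honesty-checked in its own
tests, and a fixed true-weight score isolates the property each suite
measures from weight-estimation noise. The acceptance script runs the full
pipeline (including the K = 100 cross-fit) once at n = 20,000.

## Known limitations

- Predictor-substitution SEs understate stage-1 uncertainty (documented
  above); the bootstrap option is the remedy when CIs matter.
- The weighted-median bootstrap redraws ratios rather than the underlying
  exposure/outcome beta pairs, a simplification consistent with the
  first-order SE convention used throughout.
- MR-Egger under weak instruments (violated NOME) attenuates; the median-F
  diagnostic should be consulted before interpreting the slope.
- The generator's marginal/conditional (non-collapsibility) gap is small at
  default effect sizes but would grow with large direct or confounder
  effects on the outcome.
- Reverse-direction MR (outcome on exposure) is out of scope.
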