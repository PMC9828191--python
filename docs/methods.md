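# Methods

## Model

Relative fitness — individual absolute fitness (here, fruit count or a
proxy) divided by its population mean, so mean 1 by construction — is
regressed on two covariate blocks. Standard traits (morphology, phenology)
enter as ordinary covariates. The volatile block of q emission rates enters
only through r learned composite covariates: for axis k, the composite
score of individual i is Σ_l w_kl z_il, where z are the volatiles centered
and scaled to unit SD (n−1 denominator) and w_k is a weight vector. The
linear predictor is

    w_i = alpha + x_i' beta + sum_k (z_i' w_k) b_k,    eps_i ~ N(0, sigma^2)

Gaussian error on relative fitness is assumed throughout, matching the
standard regression formulation of selection analysis; no random effects.
The slopes beta (and b_k) are selection gradients: partial derivatives of
relative fitness with respect to phenotype.

With a single fitness response and r = 1, the product b·w can realize any
coefficient vector, so the rank-1 model spans the same mean structure as
the full multiple regression; what differs is the induced prior (a scale
mixture that concentrates on one dominant direction) and the
interpretability of the axis. With r = q and weak priors the two models
coincide up to Monte-Carlo error — a property the test suite and the
acceptance studies verify. Ranks between 2 and q−1 are supported for
fitting and prediction, but individual axes are then only identified up to
rotation and are flagged accordingly.

## Priors and sampling

Conditionally conjugate priors keep the whole model Gibbs-sampleable:

- intercept and all slopes: independent Normal(0, `prior_sd_beta`²) on the
  standardized-covariate scale (default SD 1 — weak for gradients, which
  are rarely above 0.5 in magnitude on this scale, yet proper enough to
  regularize p > n multiple regressions);
- raw axis weights: independent Normal(0, `prior_sd_weights`²), default 1;
- residual variance: inverse-gamma(0.01, 0.01).

One Gibbs scan updates (alpha, beta, b) jointly from their multivariate
normal full conditional given the weights; sigma² from its inverse-gamma
full conditional; then each axis's weight vector from its multivariate
normal full conditional (the model is linear in w_k when the slopes are
fixed). All Gram matrices are precomputed, so per-iteration cost is
independent of sample size. Defaults: 2 chains, 1000 warmup + 1000 kept
draws, thin 1; a warning is logged when any split R-hat exceeds 1.1
(R-hat and bulk ESS via arviz). All covariates are standardized internally;
reported slopes are mapped back to the original measurement scales.

## Identification of the bilinear term

The axis term is invariant under (w, b) → (−w, −b) and (c·w, b/c). Three
post-processing steps make posterior summaries meaningful:

1. **Scale**: every stored draw is rescaled to ‖w_k‖ = 1 with the magnitude
   absorbed into b_k.
2. **Chain harmonization**: with a well-identified axis each chain settles
   into one of the two equivalent sign modes chosen by its random
   initialization; chains are flipped as whole blocks so their median
   weight vectors share a hemisphere. This removes an initialization
   artifact only.
3. **Per-draw sign alignment**: for weight summaries, draws are flipped so
   each draw's weight vector has nonnegative dot product with the
   element-wise median weight vector (iterated to a fixed point).

Step 3 is a relabeling that would manufacture sign coherence if applied
before computing evidence statistics: under no selection the chain itself
flips between the two modes, and that mixing is exactly what makes the
posterior support statistic honest (≈ 0.5–0.8 at null) and lets credible
intervals straddle zero. The axis gradient is therefore summarized in the
natural parameterization (after step 2, before step 3); the per-draw
relabeling is stored alongside the aligned draws so both views are exact.
Back-projected per-compound gradients (β\*_l = Σ_k w_kl b_k) are products
of jointly flipped factors and are invariant to all three steps, as are
predictions.

## Reported quantities

- Variance-scaled gradient: slope × trait SD (n−1), computed per draw and
  then summarized; for the axis the realized SD of that draw's axis scores
  is used (the axis has no population scale of its own).
- Mean-scaled gradient: slope × trait mean; reported for ratio-scale traits
  and for back-projected volatile gradients, not for the axis, which is not
  on a ratio scale.
- Posterior support: max(P[β>0], P[β<0]), draws at zero split equally;
  always in [0.5, 1]. For a continuous posterior the probability that a
  gradient is exactly nonzero is trivially 1, so sign consistency is the
  meaningful operationalization.
- Credible intervals: equal-tailed 95% quantile intervals; they contain the
  posterior median by construction.
- Explanatory r²: squared Pearson correlation between posterior-mean
  in-sample predictions and observed relative fitness — deliberately the
  same functional form as the cross-validated predictive r², so the two are
  comparable. Cross-validation re-estimates everything per training fold
  (weights, slopes, standardization constants); folds are seeded uniform
  random partitions drawn after a canonical row sort, so fold membership is
  invariant to input row order. Relative fitness is computed once from the
  full dataset and held fixed across folds: it is a population-level
  response definition, not a fitted quantity, and re-deriving it per fold
  would make held-out responses incomparable across folds.
- Method agreement r_β: Pearson correlation between back-projected and
  direct multiple-regression per-volatile gradients, on the mean-scaled
  scale.
- Among-dataset variance: σ²_βc = Var(posterior-mean gradients among
  datasets; n−1) − mean(posterior variances). The posterior variance of
  each estimate serves as its squared standard error. σ²_βc is reported
  as-is (it may be negative — an honest moment estimator) and the derived
  SD truncates at zero. Mean-scaled gradients are the meta-analyzed
  quantity: their dispersion is in units of the strength of selection on
  fitness itself. Compounds are matched across datasets by column name;
  compounds absent from some datasets are skipped with a log entry.

## Synthetic data

The generator emulates the statistical structure of scent-selection data:

- **Volatiles**: exp(μ + s·(fΛ' + e)) with 3 latent standard-normal factors
  per individual, loadings Normal(0, 0.6²) and compound noise
  Normal(0, 0.5²) — all-positive, right-skewed, and correlated in families,
  as biosynthetically linked compounds are. Defaults: 22 volatiles, the
  modal count in published scent-selection datasets.
- **Standard traits**: multivariate normal, exchangeable correlation 0.3,
  mean 10 and SD 2 (an arbitrary but nonzero measurement scale so that
  mean- and variance-scaling are distinct).
- **Fitness**: the true axis score is the re-standardized weighted sum of
  standardized volatiles with a unit-norm weight vector; relative fitness
  is 1 + g·score + Σ g_j·z(trait_j) + Normal(0, 0.3²), renormalized to
  mean 1. In gaussian mode this renormalized linear model *is* the
  response, so the generating gradients are exact up to the 1/mean rescale
  recorded in the truth record (`realized_*` entries); the nonnegative
  absolute-fitness column is a zero-truncated display proxy, and re-deriving
  relative fitness from it (as the text loader does) attenuates realized
  gradients by a few percent at default noise. A poisson mode draws fruit
  counts with mean `mean_fruits · max(0, linear predictor)` for robustness
  checks.
- Default sample size n = 200 and gradient 0.3 put the axis at roughly a
  10-SE effect — clearly detectable, as in the better-powered published
  datasets.

What the generator does *not* emulate: measurement error in emission rates,
zero-inflated volatiles (compounds absent in some individuals),
non-Gaussian fitness tails, or any pollinator mechanism. Passing
calibration on these data shows the estimator does what it claims under its
own assumptions, not that those assumptions hold in the field.

## Calibration studies (scripts/acceptance.py)

Problem sizes were chosen to make each study statistically informative at
desk scale: 20 datasets (n = 200, 6 volatiles, 2 standard traits) for the
full-rank equivalence; 200 replicates at 500/500 chain length for interval
coverage; 100 replicates at the generator's default shape for null
calibration; 500 replicates of 10-dataset collections for the
corrected-variance estimator. The full-rank study summarizes agreement by
the pooled correlation and by the maximum |difference|/MCSE over all 120
volatile-dataset pairs; note that the maximum of ~120 calibrated z-scores
has expectation ≈ 3, so values near 3 indicate exact agreement, not
failure.

## Numerical and degenerate-input choices

- Sums of squares are computed from precomputed Gram blocks; the residual
  sum of squares is floored at 1e-300 before the inverse-gamma draw.
- Zero-variance volatile columns are removed at load time (logged);
  zero-variance standard traits are an error (no meaningful gradient).
- Missing data: listwise deletion of individuals, never imputation.
- All-zero fitness is a degenerate-fitness error; individual zeros are
  legal. Volatiles are used on the scale provided — no automatic log
  transform; transformation is the user's decision.
- Chains are seeded by spawning independent streams from the configured
  seed; identical configurations reproduce results bit-for-bit.

## Limitations

- Linear (directional) gradients only; no quadratic or correlational
  selection.
- Gaussian fitness likelihood; count likelihoods and multiple fitness
  components are out of scope.
- Rank > 1 axes are not rotationally identified; only predictions and
  back-projections are interpretable there.
- The among-dataset variance estimator is the moment estimator; no
  REML/weighted random-effects meta-analysis.
- Numerical agreement with results produced by other samplers can only be
  approximate, since priors and covariate scalings differ between
  implementations.
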