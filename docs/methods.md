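# Methods

This note records the statistical conventions, numerical choices and
known limitations of `dynomo`. Everything stated here is either a design
decision of the package or a property its own tests and
`scripts/acceptance.py` compute; nothing is an external empirical claim.

## Model classes and estimation

Supported families and links (the mean response is μ = g⁻¹(η)):

| family   | link       | g(μ)        | g⁻¹(η)            |
|----------|------------|-------------|-------------------|
| gaussian | identity   | μ           | η                 |
| binomial | logit      | log(μ/(1−μ))| e^η/(1+e^η)       |
| poisson  | log        | log μ       | e^η               |
| gamma    | reciprocal | 1/μ         | 1/η               |
| cox      | —          | —           | S(t|x), see below |

The gamma family uses the plain reciprocal link μ = 1/η (the convention
of R's `Gamma()` default). A log link is also accepted for gamma.

**OLS.** β̂ = argmin‖y − Xβ‖² via pivoted QR; dispersion σ̂² = RSS/(n−p);
Σ̂ = σ̂²(XᵀX)⁻¹. Rank deficiency is reported with the names of the
collinear columns (from the QR pivot order).

**GLM / IRLS.** Working response z = η + (y−μ)/(dμ/dη), weights
w = (dμ/dη)²/V(μ), iterated weighted least squares until
max|Δβ| < 1e−9 (at most 50 iterations, starting from β = 0 with the
intercept at g(ȳ)). Dispersion φ is fixed at 1 for binomial/Poisson,
RSS/(n−p) for gaussian, and the Pearson estimate X²/(n−p) for gamma;
Σ̂ = φ(XᵀWX)⁻¹. Diverging coefficients (max|β| > 1e8, the signature of
separation) raise a dedicated error carrying the iteration trace, as
does non-convergence.

**Cox.** Newton–Raphson on the partial log-likelihood with step-halving
(the likelihood never decreases between iterations), covariates centered
at their column means for numerical stability. Ties use the Efron
correction by default; Breslow is available. Σ̂ is the inverse observed
information at β̂. When no two events share a time the two corrections
coincide and a vectorised suffix-sum evaluation (O(np²)) is used; with
ties, an explicit per-event-time loop. The baseline cumulative hazard is
the Breslow estimator on the centered scale,
dΛ̂₀(t_j) = d_j / Σ_{i∈R(t_j)} e^{(x_i−x̄)β̂}, with at-risk counts
recorded at each distinct event time. At β = 0 this reduces to the
Nelson–Aalen estimator, which is how the hand-checked three-subject
fixture in the tests validates it.

## Prediction intervals

For a profile x\*: η̂ = x\*ᵀβ̂, se(η̂) = √(x\*ᵀΣ̂x\*), interval
η̂ ± u·se on the linear scale, then g⁻¹ applied to the estimate and both
limits (swapped when g⁻¹ is decreasing, as for the reciprocal link; an
interval spanning η = 0 under that link has no defined image and errors).
The critical value u is a standard-normal quantile when the dispersion
is known (binomial, Poisson, Cox) and a Student-t quantile on n−p
degrees of freedom when it is estimated (gaussian, gamma). Values
outside the observed covariate range warn (extrapolation) rather than
error, because the interactive controls are bounded anyway.

Cox survival: S(t|x) = exp(−Λ̂₀(t)·e^{(x−x̄)β̂}) as a right-continuous
step function. Pointwise intervals for S(t|x) are built on the
log-cumulative-hazard scale — Var(Λ̂) combines the Poisson-type baseline
term Σ_{t_j≤t} d_j/S₀(t_j)² · e^{2η̂c} with the coefficient term gᵀΣ̂g,
g = ∂Λ̂/∂β — and back-transformed, so they respect [0, 1] and are
asymmetric near the boundaries. Prediction beyond the last observed
event time errors (no baseline information there).

## Design matrices

* Factors use treatment contrasts; level order is the lexicographic sort
  of observed labels (first = reference), overridable per variable. This
  mirrors the default of R, under which the classic worked examples were
  originally reported, so coefficient signs and labels are directly
  comparable.
* Restricted cubic splines use the truncated-power parametrization with
  (t_k−t₁)² normalization and default quantile knots (for k = 5 at
  probabilities 0.05, 0.275, 0.5, 0.725, 0.95) — the conventions of
  Harrell's regression-modelling framework, chosen so spline coefficient
  tables match the standard R output for the same data. Knots are frozen
  on the term at fit time and serialized with the model.
* Interactions (order ≤ 3) are elementwise products of the constituent
  main-effect columns; the main effects must be present.
* Missing data: complete-case deletion with the dropped count logged and
  recorded. No imputation.
* The intercept is always present for non-Cox models; Cox designs have
  none.

## Nomogram geometry

The classical ruler-length rule, range(Xᵢ)·βᵢ scaled by the maximum such
product, is defined only for linear covariate terms. `dynomo`
generalises it to the **contribution span**: max − min of the term's
contribution to η over the observed support (covariate endpoints, all
factor levels, a 100-point grid for splines and stratified rulers). The
largest-span term maps to exactly 100 points; every other ruler is
scaled proportionally, and each ruler is offset so its minimum
contribution sits at 0 points. Total points map back to the response
through η = η₀ + total/scale and g⁻¹ (for Cox, the displayed scale is
the relative hazard e^{(x−x̄)β}); by construction the summed points at
any input reproduce the prediction module's point estimate, a
consistency the tests check to 1e−6 on random inputs for every family.

Interactions involving at least one factor are drawn as one covariate
ruler per factor-level combination (stratified rulers sharing one scale
and offset); all factor-only terms that share variables collapse into a
single combined-level ruler. A covariate×covariate interaction has no
faithful one-dimensional ruler and raises an explicit unsupported-layout
error pointing to the dynamic interface. Response rulers carry up to 7
"nice" tick values across the achievable response range. SVG output is
assembled from strings with fixed formatting, so identical layouts are
byte-identical — verified against a reviewed golden file.

## Interactive layer and bundles

Sliders span exactly the observed covariate range with step = range/100
rounded to a presentable 1–2-significant-figure increment; drop-downs
list factor levels with the mode as default and the mean as the slider
default. The app layer performs no statistics: every displayed number is
produced by a prediction-module call (a test replaces that layer with a
mock to enforce it). Survival curves are drawn with opacity
max(0.1, at-risk fraction), a documented choice for encoding estimate
support over follow-up; the floor keeps late follow-up visible.
Scenarios are appended, never merged, so indices are stable.

Bundles contain the serialized model (coefficients, covariance,
dispersion, variable metadata, frozen spline knots, Cox baseline), the
control config, an entry script and a sha256 manifest. They are
hermetic: served predictions depend only on `model.json`, which the
tests verify by deleting the training CSV and comparing bit-for-bit.

## Synthetic data

The generator draws covariates from declared uniform/normal
distributions and factors from declared level probabilities, forms
η = Xβ with stated coefficients, and draws the response from the family
(gaussian σ = 1; Bernoulli(logit⁻¹η); Poisson(e^η); Gamma with shape 2
and mean 1/η; exponential event times with hazard 0.1·e^η censored
Uniform(0, 30)). Defaults for the validation suites use one Uniform(0, 2)
covariate and one balanced binary factor with moderate effect sizes
(|β| between 0.3 and 1), the regime of the worked examples. The
generator emulates correctly specified models with independent rows; it
does not emulate model misspecification, covariate correlation,
informative censoring, measurement error or missingness, so passing
recovery/coverage tests demonstrate the estimators and intervals are
correct *under the model*, not robustness to its violation.

Validation problem sizes: coefficient recovery uses n = 2000 per
replicate, 200 replicates per family in the test suite (50 in the
acceptance script), asserting |β̂−β| < 3·SE componentwise in ≥ 95% of
replicates; interval coverage uses 1000 logistic replicates at n = 500,
asserting empirical coverage in [0.92, 0.97]; layout consistency uses 50
random inputs per model class at tolerance 1e−6.

## Worked-example data

The lung-cancer table (228 subjects) is taken from lifelines' bundled
copy of the North Central Cancer Treatment Group data; the Titanic table
(1309 passengers) from the installed R `carData` package via `Rscript`
(`survived`, `sex`, `age`, `pclass`). Both are cached as plain CSV. The
horseshoe-crab and ragweed tables are downloads from pinned archive
URLs; their sha256 is recorded beside the cache on first fetch. Checks
that need a dataset which cannot be materialised fail with an explicit
`DatasetUnavailableError` — they are the only parts of the suite with an
external dependency; everything else runs on synthetic data. The crabs
fit is conditional on the colour→dark/light recoding shipped in the
source data; the ragweed response is pre-transformed to √(pollen count)
at load, and its spline reproduction is conditional on the default
quantile knots described above.

## Known limitations

* No offsets, weights, ordered/polynomial contrasts, or penalized
  smoothers; no intercept suppression.
* No robust/sandwich covariance, stratified Cox, time-varying covariates
  or frailty terms.
* Mean-response intervals only — no prediction intervals for new
  observations and no simultaneous bands.
* Static layout refuses covariate×covariate interactions (by design);
  spline×factor rulers are stratified and can be visually busy.
* The reciprocal-link mean is undefined where the interval spans η = 0;
  the package errors rather than guessing.
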