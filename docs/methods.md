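# Methods

## Model and scope

The package studies what happens to exposure–outcome regression coefficients
when an analysis is restricted to selected units, S = 1, where S is a
*collider*: a variable affected by both the exposure X and the outcome Y.
The organising assumption is the log-additive selection model

    log P(S = 1 | X, Y) = δ₀ + δ₁X + δ₂Y + δ₃XY,

valid only where the right-hand side is ≤ 0. Its key property is that the
exposure–outcome interaction δ₃ fully determines collider bias on the
odds-ratio and log-odds-coefficient scales (bias δ₃), the linear-regression
slope scale (bias δ₃σ², with σ² the residual variance), and the
Poisson-regression slope scale (bias δ₃, with the conditional outcome
remaining Poisson). The risk-ratio scale is the exception: the conditional
risk ratio depends on δ₂ as well, so absence of an interaction does not
guarantee an unbiased risk ratio. All of these statements extend to
non-linear selection main effects g₁(X), g₂(Y), to an exposure-dependent
interaction coefficient g₃(X) (OR distortion exp{g₃(x+1) − g₃(x)}), to a
general mean function m(x; β) for the linear case, and per-coefficient to
vector exposures. The `formulas` module implements these closed forms; the
general mean function is evaluated pointwise for a user-supplied m, with no
regularity demanded of m beyond finiteness at the evaluation point.

## What the simulator emulates

`simulate.draw_cohort` generates (X, Y, S) under the crossings of three
outcome models — logistic, linear, Poisson, all with β₀ = 0, β₁ = 0.2 and
(linear only) σ = 0.5 — and four selection mechanisms sharing the linear
predictor δ₀ + 0.3X + 0.3Y + δ₃XY:

* logistic: P(S=1) = expit(lp);
* probit: S = 1{S′ > 0}, S′ ~ N(lp, 1.6²);
* double-threshold: S = 1{S′ < r₁ or S′ > r₂} — selection in *both tails*
  of the latent variable (e.g. clinic attendance triggered by extreme values
  in either direction);
* log-additive: P(S=1) = exp(lp).

The exposure is Bernoulli(0.3) by default; a normal exposure is supported.
The latent residual scale 1.6 makes probit coefficients comparable in
strength to the logistic model's. The interaction grid used throughout is
δ₃ ∈ {0, ±0.1, ±0.2, ±0.3, ±0.4, ±0.5}.

These defaults describe a deliberately clean world: a single scalar
exposure, no confounding, no measurement error, selection depending on
(X, Y) only, and correctly specified outcome regressions. Passing tests
therefore certify the bias *mechanism* and its estimability, not robustness
to the additional complications of real cohort data (item missingness,
confounding, longitudinal attrition models), which are out of scope.

### Validity and truncation

With a bounded outcome (binary Y) the log-additive model is either valid on
the whole support or rejected outright. With unbounded outcomes (normal,
Poisson), extreme Y can push exp(lp) above 1; `draw_cohort` then truncates
the probability at 1 and warns with the truncated fraction, which is also
stored on the cohort (`n_truncated`). Tests that rely on exact log-additive
theory assert this count is (essentially) zero, and the calibration routine
prefers intercepts inside the valid region whenever the target fraction is
attainable there.

### Calibration of the selection fraction

`calibrate_selection` tunes δ₀ by Brent root-finding on the Monte-Carlo
expectation of P(S=1) over a dedicated presample of 10⁶ (X, Y) draws with a
fixed internal seed (tolerance 10⁻³ on the fraction, configurable). For the
double-threshold model δ₀ is pinned to 0 and the cut points are set to the
α/2 and 1−α/2 empirical quantiles of the latent S′, α being the target
fraction — at 50% these are the first and third quartiles. For the
log-additive family on a bounded support, targets above the valid-model cap
raise an error stating the attainable range.

## Fitting

Outcome models are fitted by GLM maximum likelihood (statsmodels IRLS) on
all units or the selected subset, with model-based standard errors. The
log-additive selection model is fitted by applying log-link
Poisson-regression estimating equations to the binary indicator S on
covariates (1, X, Y, XY): the Poisson score equations evaluated at a 0/1
response are exactly the quasi-likelihood equations of the log-additive
binary model. Fitted probabilities above 1 are permitted during this fit —
they are expected under misspecification — and their count is reported in
`FitResult.extras["n_fitted_gt1"]`. Starting values are δ₀ = log(mean S)
and zeros; convergence tolerance 10⁻⁸, at most 100 IRLS iterations.
Non-convergence or separation yields `converged=False` with a diagnostic
message, never a silent estimate. The interaction column is the raw product
X·Y (no centering — δ₃ is defined on the raw scales).

## The numerical asymptotic study

`study.run_bias_experiment` approximates population (limiting) values of
estimators by single large-cohort Monte Carlo: for each δ₃ on the grid it
calibrates selection, draws one cohort, computes the collider bias
β̂₁(selected) − β₁ and the log-additive interaction estimate δ̂₃, then
regresses bias on δ̂₃ (and on the true δ₃) by OLS *with* intercept.
The intercept is kept because misspecified mechanisms leave a small residual
bias even at δ₃ = 0, and forcing the line through the origin would distort
the slope.

Design choices that matter:

* **Problem size.** The default is n = 5×10⁵ per grid point, a
  workstation-scale stand-in for the very large single datasets that the
  limiting-value argument contemplates; all tolerances in the tests were
  set for this n and are config-overridable.
* **Common random numbers.** Every grid point (and every selection
  fraction) of a given outcome×selection pair reuses the same derived seed,
  so the underlying (X, Y) draws and selection uniforms are shared. Cohort
  noise that is common across grid points is absorbed by the regression
  intercept and cancels in cross-fraction contrasts, sharply reducing the
  variance of slope estimates without biasing any single point. Seeds are
  derived as CRC32(master seed | label) < 2³¹, making experiments
  reproducible and parallel-safe by construction.
* **One cohort per grid point** rather than replicate averaging; the
  Monte-Carlo uncertainty reported per point (`mc_se`) is the outcome-fit
  standard error.

A noteworthy exact identity: with binary X and binary Y both the selected
logistic fit and the log-additive fit are saturated, so
β̂₁(selected) = β̂₁(all) + δ̂₃ holds *exactly* in every finite cohort.
Combined with shared draws across the grid this makes the fitted slope for
the logistic outcome equal to 1 up to floating-point error; for linear and
Poisson outcomes no such identity exists and the slope carries genuine
Monte-Carlo error. The near-linearity of bias in δ̂₃ is a binary-exposure
phenomenon: with a normal exposure the relationship is generally curved,
so the study reports residual diagnostics there and asserts no slope.

## Inverse probability weighting

`ipw.ipw_estimate` fits a weight model for P(S=1|X,Y) on the full cohort,
weights selected units by the inverse fitted probability, and solves the
weighted outcome estimating equations. Weight models of increasing
flexibility — interaction-free logistic, logistic with interaction, the true
probabilities — demonstrate that IPW removes collider bias only when the
weight model can represent the XY interaction; an interaction-free model can
even overshoot. Standard errors on weighted fits are naive model-based ones
(no sandwich correction): the package's claims concern point-estimate bias.
Stabilized weights (multiplied by the marginal selection fraction) change
point estimates not at all for models with an intercept; an optional
trim quantile exists for small-sample robustness and is off by default.

## Numerical verification choices

* Exact enumeration over the four cells of binary (X, Y) is the oracle for
  odds-ratio and risk-ratio formulas (machine-precision agreement required,
  tolerance 10⁻⁸ relative over randomized valid-parameter sweeps).
* Gauss–Hermite quadrature (96 nodes) of the tilted normal density is the
  oracle for the linear-model conditional mean (tolerance 10⁻⁸).
* Truncated summation up to max(200, mean + 20·√mean) of the tilted Poisson
  mass is the oracle for the conditional Poisson rate (tolerance 10⁻⁸
  relative).
* Randomized valid parameters are drawn by sampling (δ₁, δ₂, δ₃) and
  shifting δ₀ below −max(δ₁x + δ₂y + δ₃xy) over the support.

## Known limitations

* The log-additive model's validity region makes high selection fractions
  unattainable without truncation for some parameter combinations; the
  calibrator reports the attainable range rather than silently truncating on
  bounded supports.
* Weighted and unweighted standard errors are model-based; inference (as
  opposed to bias quantification) would require robust variance estimation.
* The double-threshold mechanism compresses the induced log-additive
  interaction scale, so slope estimates there are intrinsically noisier than
  under logistic or probit selection at the same n.
* No support for missing-data mechanisms beyond the selection indicator,
  for survival outcomes, or for instrumental-variable analyses.
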