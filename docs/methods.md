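# Methods

This note documents the statistical machinery implemented in `qboost`,
the choices made where the design was genuinely open, and what the
synthetic data generators do and do not establish.

## Quantile boosting

**Objective.** Each border of a prediction interval is one additive
quantile regression model at level τ, estimated by minimizing the
empirical check-loss risk `(1/n) Σ ρ_τ(y_i, η_i)` with component-wise
functional gradient boosting. The negative gradient of the check loss is
piecewise constant: τ where `y > η`, τ − 1 where `y ≤ η`. At the
measure-zero tie `y = η` we assign τ − 1; any fixed convention works,
this one is used consistently.

**Algorithm.** The predictor is initialized to the empirical τ-quantile
of the response (the risk minimizer over constants; `numpy` type-7
linear-interpolation quantiles throughout). Per iteration every
base-learner is fitted to the current negative gradient by (penalized)
least squares; the learner with the smallest residual sum of squares is
updated by `step_length` times its fitted increment (default ν = 0.1,
the conventional value for component-wise boosting — it interacts only
with `m_stop`). Ties are broken toward the lowest spec index, making the
trajectory fully deterministic; identical data, configuration and seed
reproduce bit-identical models.

**Risk descent.** The training risk decreases monotonically during the
productive phase of boosting, but *strict* monotonicity cannot hold for
a fixed-step method on a kinked loss: once converged, a full step can
overshoot the kink and the risk enters a tiny oscillation of order
`step_length × gradient scale` (observed amplitude ~3·10⁻⁵ on risks of
order 0.2). Tests therefore assert descent up to a 0.1% relative
tolerance rather than strict monotonicity.

**Base-learners.**

* *linear*: OLS of the gradient on the mean-centered covariate plus an
  intercept. Centering lets the intercept parts accumulate cleanly; they
  are folded into the reported model intercept at summary time.
  Categorical covariates form one learner per dummy block (reference =
  first observed level), so a whole factor enters or stays out of the
  model together, with per-level effect estimates.
* *pspline*: cubic B-splines on 20 equidistant interior knots over the
  covariate's observed range with a second-order difference penalty. The
  penalty weight is calibrated **once, from the basis alone**, so the
  smoother's effective degrees of freedom (trace of the hat matrix)
  equal 4 — weak learners of equal effective df keep the selection step
  fair. Calibration solves `Σ 1/(1 + λ s_k) = df` over the generalized
  eigenvalues `s_k` of the penalty with respect to the basis Gram
  matrix. Prediction clips new covariate values to the training range.
* *subject intercept / subject slope*: ridge-penalized per-subject
  constants, or per-subject slopes in a designated covariate (age),
  shrunk toward zero, with the ridge weight calibrated to the same
  effective-df target (default 4; `Σ z_i²/(z_i² + λ) = df` over
  subjects). Together with boosting's iterative shrinkage and early
  stopping these act as regularized random intercepts and slopes. An
  L1-flavoured construction for such learners exists in the literature
  but without operational detail; the ridge-in-boosting form is this
  package's documented choice, with early stopping supplying the
  sparsity role. Subjects unseen at prediction time (or predictions with
  `include_subject_effects=False`) contribute exactly zero — the
  expected mean of the random effects.

**Early stopping.** `m_stop` is the central tuning parameter. Selection
minimizes the mean out-of-sample empirical risk over m = 1…`m_max`,
where the out-of-sample risk comes from a held-out validation set,
k-fold cross-validation, row bootstrap (out-of-bag rows), or
subject-wise bootstrap (out-of-bag subjects — duplicated subjects in a
resample are relabelled as distinct clusters). The validation risk is
recorded after every iteration; an optional `patience` argument stops
tracking once the risk has not improved for that many iterations, which
truncates the search deterministically without changing the argmin in
practice.

For the simulation study the defaults are `m_max` = 12000 (linear setup)
and 20000 (non-linear) with patience 1500: with ν = 0.1 and extreme
quantile levels the gradient magnitudes are small (|τ|, |1−τ|), and the
validation risk keeps improving until roughly 5–6k (linear) and 9–13k
(non-linear) iterations. Smaller caps would leave the fit visibly short
of its validation optimum.

## Intervals and coverage

`build_pi` evaluates the two fitted borders at new covariates. Where the
fitted lower border exceeds the upper one (quantile crossing — an
estimation artifact), the borders are swapped and the event is counted
in `crossing_count`; repair is never silent. A non-symmetric τ pair is
allowed with a warning. The naive baseline interval is the pair of
unconditional empirical quantiles of the training response (type-7
convention), identical for every x.

Sample coverage averages indicators over a fresh sample with one
interval per observation; conditional coverage averages fresh responses
drawn at a single fixed covariate point against that point's single
interval. Both report the binomial standard error
`sqrt(p̂(1−p̂)/n)`. The two notions genuinely dissociate: on a
heteroscedastic process the naive interval attains ≈95% sample coverage
while over-covering where the conditional spread is small and
under-covering where it is large.

## Simulation study

Two location-scale processes with ε ~ N(0,1) and four informative
covariates:

* linear: x ~ U(0,1)^p, mean `1.5 − 3x₁ − 2x₂ + 3x₃ + 5x₄`, scale
  `1 + 0.5(x₁+x₂+x₃+x₄)`;
* non-linear: x ~ U(0,3)^p, mean `2 + 3 sin(2x₁/3) + 1.5 log(x₂) + 2x₃ −
  2x₄`, scale `0.7 + 1.5(x₁−1.5)² + 0.5(x₂+x₃)`. The scale is read as an
  additive expression (no square root); this reading is isolated in a
  single function so a corrected form changes one place. `log(x₂)` has a
  probability-zero singularity at exactly 0; such draws are resampled.

True conditional quantiles are `μ(x) + σ(x)·Φ⁻¹(τ)`. The harness runs,
per simulation run, a fresh training (n = 2000) and validation
(n = 5000) sample, fits both borders with validation-selected stopping,
and estimates conditional coverage at five fixed test points from 10000
fresh responses each; results average over runs (100 by default) with
run-to-run Monte-Carlo standard errors. Exact test-point coordinates are
not externally fixed, so the package uses a deterministic grid at
10/30/50/70/90% of the support in every coordinate — the third point is
the exact support center. A plug-in "oracle" method substitutes the true
quantiles into the same harness; it must (and does) return 1 − α at
every point, separating harness errors from estimator bias.

Estimation bias is visible exactly where it should be: at extreme
quantiles the boosted borders are shrunk, and near the support
boundaries and strongly curved regions of the quantile surface the
smoothing bias of df-4 learners shows up as coverage a few tenths of a
percentage point off nominal — mirroring the degradation of
boundary-point coverage that the validation framework is designed to
expose. Run-to-run coverage at a single point has substantial dispersion
(sd up to a few percentage points in the non-linear setup), which the
reported MC standard errors quantify.

## Synthetic cohort

The generator emulates a birth-cohort schema: per child, BMI at birth
and at age two, maternal BMI and pregnancy BMI gain, sex, area,
breastfeeding, smoking during pregnancy, education level (4 levels), and
one to three later BMI measurements at jittered visit ages around 4, 6
and 10 years (attendance probability 0.9 per visit, at least one visit
forced, jitter U(−0.5, 0.5) years).

The response is a location–scale–skew family with exact quantiles:

* location: quadratic growth curve in age (dip and rebound around six),
  mildly quadratic effect of the age-2 BMI, linear maternal-BMI effect,
  small education effects; sex, area, breastfeeding, birth BMI and
  maternal BMI gain carry exactly zero effect (sparse truth);
* scale: linear in age, multiplied up for smokers (smoking widens the
  interval rather than shifting its center — its effect has opposite
  signs on the two borders);
* skewness: a two-piece (split) normal error with right scale
  `σ(1+γ(age))`, γ = 0 until age six and ramping linearly to 0.6 at age
  ten — BMI right-skew appearing after age six;
* within-child correlation: random intercepts (sd 0.8 kg/m²) and random
  age slopes (sd 0.12 kg/m² per year).

The two-piece construction was chosen over arbitrary transforms because
its quantile function is closed-form, so the truth oracle is exact. For
a *new* child the random effects must be integrated out; with γ = 0 the
marginal is Gaussian (closed form), otherwise the marginal CDF is
computed by 64-node Gauss–Hermite quadrature and inverted with Brent's
method — deterministic to ~10⁻¹⁰, verified against 10⁶-draw Monte Carlo.

Magnitudes are a realistic construction of this package, **not**
calibrated to any real cohort; the generator reproduces the qualitative
signatures above, so passing tests show the methodology behaves
correctly on data with these features — not that any particular real
population is described.

## Cohort pipelines

Cross-sectional: response = BMI at the ~age-4 visit; non-linear effect
for the age-2 BMI, linear effects for everything else; 10-fold CV over
*children*, `m_stop` tuned by 25-replicate bootstrap on each training
fold; held-out intervals and a covariate-by-τ effect table (blank cell =
never selected) are reported. Longitudinal: all visits, plus a smooth
age effect and subject intercept/slope learners; tuning by subject-wise
bootstrap; held-out children are treated as new (subject effects zero).
Folds always partition children, so child-level leakage is structurally
impossible. The cross-validated empirical check loss is the comparison
measure between methods — it ranks algorithms but cannot certify
coverage.

The goodness-of-fit diagnostic simulates responses from the
piecewise-linear inverse of a fitted τ-grid (19 levels by default; the
grid is refitted rather than interpolated from two borders),
isotonizing non-monotone rows with a count, extrapolating tails with the
outermost segment slopes, and compares pooled simulated vs. observed
quantiles over a central probability grid (optionally per visit age).
This is deliberately the simple simulate-and-compare form; a full
formal diagnostic methodology for conditional quantile models is out of
scope.

## Problem sizes used in the checked experiments

The automated experiments use: 100 runs (linear) and 20 runs
(non-linear) for the coverage study in the test suite, 100 runs for both
setups in `scripts/acceptance.py`; 20 replicates at n = 1000 for the
p = 500 sparsity check; and a 2000-child cohort with 3 folds, 6
bootstrap replicates and `m_max` = 3000 for the longitudinal coverage
closure. These sizes were chosen to keep a desk-scale run while leaving
the selection machinery past its risk plateau.

## Known limitations

* No standard errors or tests for effect estimates — shrinkage makes
  them unavailable by construction; the focus is prediction.
* Quantile crossing is repaired pointwise (swap-and-flag), not by joint
  monotone estimation across τ.
* The subject-effect learners are ridge-based; a dedicated L1
  random-effect learner could behave differently for strongly sparse
  subject effects.
* Intervals are pointwise per age, not simultaneous over a trajectory.
* P-spline prediction clips covariates to the training range; effects do
  not extrapolate.
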