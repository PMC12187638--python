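# Methods

This note documents the models implemented in `thermoforage`, the defaults
and units of their tunable parameters, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## The additive-model engine (`thermoforage.gam`)

Every fitting stage uses one penalized-spline engine.

**Basis.** Smooth terms use a natural cubic regression spline parameterized
by its values at k knots placed at quantiles of the covariate (default
k = 5, configurable 3–20). The penalty is a divided-difference quadratic
form of order 2 on the knot values: on an evenly spaced knot grid it equals
the sum of squared second differences of the fitted values at the knots
exactly, and on any grid it annihilates linear functions, so the penalty
null space is the straight line and the smooth collapses to ordinary linear
regression (EDF → 1) as its smoothing parameter grows. This value-based
penalty was chosen over the integrated-squared-second-derivative form
because it admits an exact finite-difference oracle for testing while
behaving identically in the limits that matter (null space, positive
semidefiniteness). Seasonal smooths that must join smoothly across the year
boundary use a harmonic (sin/cos) basis of the 365.25-day period with a
frequency-weighted ridge penalty (weight j⁴ on harmonic j), which is
exactly periodic by construction. All smooths are constrained to sum to
zero over the training sample (cubic splines by a QR null-space
reparameterization, harmonics by column centering — the QR constraint is
ill-conditioned when column sums are already near zero), so the intercept
carries the mean.

**Random effects.** A factor random effect is a ridge-penalized block of
group indicators; a random slope adds an indicator-times-covariate block
with its own variance parameter. This is the standard mixed-model-as-
penalized-regression representation: the ridge weight λ corresponds to
σ²/σ_u².

**Fitting.** Penalized IRLS (Gaussian, binomial-logit, Poisson-log) to a
relative penalized-deviance change below 1e-8 or 200 iterations, with step
halving on the penalized deviance. Non-convergence and suspected separation
(|η| > 12 in the binomial family) are reported as notes on the fit, never
raised. Smoothing and variance parameters maximize the exact Gaussian REML
criterion, or a Laplace-approximate restricted marginal likelihood for the
other families, by bounded Brent search coordinate-wise on log λ ∈ [−10, 18]
(xatol 0.01, up to five sweeps). REML was adopted over GCV because the
variance-component tests downstream are REML-based and one criterion keeps
the engine coherent.

**Summaries.** EDF per term is the trace of the corresponding block of
(XᵀWX + S)⁻¹XᵀWX; AIC = −2ℓ + 2·EDF and BIC = −2ℓ + EDF·log n use the total
EDF as model dimension — for penalized fits the raw column count is
meaningless, and EDF-based criteria let models with different random-effect
structures be compared on one scale. Deviance explained is 1 − D/D₀ against
the intercept-only model. Prediction covariance is the Bayesian posterior
(XᵀWX + S)⁻¹φ̂.

## Performance curves (`thermoforage.curves`)

Foraging activity is zero-inflated (no workers on the trail at all, or some
count of them), so it is fitted as a hurdle: a binomial additive model of
presence (count > 0) on all rows times a Poisson additive model of the
count on the strictly positive rows. The positive-count part is fitted as a
plain (untruncated) Poisson; a zero-truncation correction would change the
conditional mean by a factor 1/(1−e^−μ), which is negligible at the counts
where the curve summaries are read (μ ≳ 5) — this approximation is
documented rather than hidden behind the default. Both parts carry a
temperature smooth (k = 5) and a nest-identity random intercept; the
"adjusted" mode adds a parametric nest-size term and a time-of-day smooth
and benchmarks predictions to the median nest size at noon. Curve summaries
are read from the combined expectation p(T)·μ(T) at the population level
(random effects set to zero):

* **peak** — argmax on a grid (default 0.1 °C) over the observed
  temperature range; ties break to the lower temperature for determinism; a
  peak at either end of the range is flagged and no optimal window is
  computed for it, because a 90 %-of-apex window is undefined without an
  interior apex.
* **optimal window** — the maximal contiguous grid interval containing the
  peak with prediction ≥ fraction × peak (default fraction 0.90).
* **emergence window** — by default the observed min/max temperature over
  active observations; a model-based alternative (temperatures where fitted
  presence crosses 0.5) is also implemented because the definition of an
  "observed average" emergence bound is ambiguous in field practice. Both
  can be requested; observed-range is the default.

Swarm (nest-defence) performance is a Gaussian additive model of swarm
speed with the same smooth structure.

**Change-point model.** The lower emergence threshold of swarming is
estimated by a two-segment hierarchical model: speed is Normal(0, σ²) noise
below a nest-specific threshold τⱼ and Normal(β(T − τⱼ), σ²) above it, with
τⱼ ~ N(μ_τ, σ_τ²). Priors: μ_τ uniform over the observed temperature range
(range-respecting and weakly informative), σ_τ and σ half-Cauchy(2),
β half-Normal(10). The posterior is sampled with an affine-invariant
ensemble sampler (32 walkers or at least 2·dim+2, 3000 iterations, 1000
warmup, differential-evolution moves) in the *centered* parameterization —
the data identify each τⱼ strongly, so sampling τⱼ directly mixes far
better than non-centered deviates. Split-R̂ and ESS are computed over walker
chains; runs with R̂ ≥ 1.05 are flagged, as are prior-dominated posteriors
(no observation below its nest's estimated threshold, or a population
posterior spanning most of its prior range). Only the lower threshold is
modeled; the upper threshold uses the order-statistics estimates (maximum
emergence temperature = liberal; median non-emergence temperature =
conservative).

## Activity budgets (`thermoforage.budget`)

Daytime is defined by solar elevation > 0 from a Cooper-declination,
local-clock (longitude-free) solar model; latitudes beyond ±66.5° are
rejected (polar day/night out of scope). Daily daytime min/max/range are
computed per nest-day, with a completeness flag when observed daytime
intervals reach 90 % (configurable) of the expected count. Available hours
for an activity are 0.5 h per observed 30-min interval with temperature
inside the window, bounds inclusive on both ends (the thresholds are
defined by activity observed *at* those temperatures). Hours are counted
over the full 24 h by default — overnight temperatures fall below the lower
threshold and contribute nothing — with a daytime-only switch; the daytime
parse applies only to the min/range summaries. Missing intervals contribute
zero hours and the day inherits its completeness flag; no infilling.

## Among-nest variance (`thermoforage.variance`)

Daily summaries are modeled with a cyclic seasonal smooth of day-of-year
(harmonic basis, k = 8) under three nest-effect structures: none, random
intercept, random intercept + slope. The random slope is on the seasonal
index cos(2π(doy − 15)/365.25) — the natural choice when the fixed trend is
seasonal; summer scores +1, winter −1. Models are ranked by EDF-based BIC.

The restricted likelihood ratio test uses a parametric bootstrap: simulate
responses from the fitted null, refit both models per replicate, statistic
= max(0, 2(ℓ_R,alt − ℓ_R,null)), p = (1 + #{sim ≥ obs})/(n_sim + 1). The
bootstrap was chosen over the analytic boundary-mixture null because it is
family-agnostic and reflects the actual refitting procedure. Because the
variance component sits on the boundary, roughly half the simulated
statistics are exactly zero. Refits maximize the exact Gaussian restricted
log-likelihood over a fixed grid of log smoothing parameters (step 2.0 for
smooths — both models move together, so coarse is safe; step 0.75 plus
near-infinite boundary values for random-effect blocks so the no-effect
limit is reachable exactly), with all bootstrap replicates solved
simultaneously per grid point via one Cholesky factor. The observed
statistic is computed on the same grid, keeping the comparison internally
consistent. Default n_sim is 10,000 for final analyses; the pipeline and
tests use 199–499 for speed.

## Colony analyses (`thermoforage.colony`)

**Effort standardization.** log10(foraging + tree trails) per nest-year
(connection trails excluded by default, switchable) is regressed on nest
size (centered at the population mean) with a per-nest random intercept and
slope. "Effort independent of size" is the back-transformed nest intercept
10^(β₀ + u₀ⱼ): the nest's predicted trail count at the population-mean
size — the only back-transformable size-free scalar per nest. Zero-trail
nest-years are dropped from the log response with a warning (a log10(x+1)
option exists behind config); the data motivating the design transform
log10 without a stated zero policy, and established nests essentially
always hold at least one trail.

**Compensation.** OLS slopes (with t and p) of mean nest size and of
standardized effort against the summer apex and winter base of each nest's
fitted seasonal daily-hours trend. No decision rule is imposed — the
scientific question is about the sign pattern (compensating colonies would
show no size trend and a negative effort trend).

**Growth.** Per nest, OLS fits of entrance-hole counts on years since first
survey: intercept-only, linear, quadratic. AICc = AIC + 2k(k+1)/(n−k−1)
with k the number of regression coefficients (1, 2, 3), so the linear model
is defined from 4 years and the quadratic from 5; shorter series omit the
model with a notice. The Gaussian ML log-likelihood is used in AIC; models
within 2 AICc units of the best are flagged supported; t-values use the
usual OLS standard errors (an exact-fit series yields a machine-bounded t).
Years are centered at the first monitored year for numerical stability of
the quadratic term.

## The synthetic-data generator (`thermoforage.synthetic`)

The generator emulates the study conditions the analyses are designed for:

* **Microclimate.** A shared baseline common to all nests — mean 10 °C with
  a ±6 °C seasonal sinusoid peaking in mid-January (southern hemisphere,
  default site latitude −32.3°) — plus a nest-specific half-sine diurnal
  bump between sunrise and sunset whose amplitude is the nest's exposure
  (defaults span 14–30 °C across a study of 11 nests, putting exposed
  summer surfaces in the mid-40s °C and shaded winter maxima near 10 °C)
  reduced by the nest's seasonal amplitude (default 8 °C) in mid-winter,
  plus stationary AR(1) noise on the 30-min grid (sd 1 °C, lag-1
  correlation 0.8 by default). Because the bump vanishes at night, the
  deterministic pre-dawn minimum is identical across nests every day — the
  premise the variance analyses probe. A per-nest seasonal sinusoid in the
  *baseline* would break that premise, which is why the seasonal parameter
  modulates the diurnal amplitude instead.
* **Activity.** Hourly daytime sampling on one mid-summer and one
  mid-winter day. Presence is Bernoulli with a double-logistic probability
  (rising and falling logistics, midpoints 15.9 / 43.1 °C, steepness
  0.5 /°C); counts given presence are Poisson with mean
  max_rate · exp(−(T − peak)²/2w²) · e^{0.04(size−32)} · 10^propensity
  (peak 29.7 °C, width 5 °C, max_rate 25 workers). Swarm speed is Gaussian
  around the same unimodal shape, floored at zero. A separate onset
  generator produces true hockey-stick threshold data (τ = 13 °C,
  between-nest sd 1 °C, slope 0.8 per °C, noise sd 0.6) for change-point
  recovery tests; responses are left unclipped there to match the Gaussian
  change-point likelihood.
* **Surveys.** Annual entrance-hole counts under flat / linear / quadratic
  trends (noise default 10 % of starting size; canonical effect sizes
  3 holes/yr and 0.6 holes/yr², the magnitudes seen in declining long-term
  nest records) and trail counts round(10^(0.3 + 0.008·size + propensity))
  with 0.05 log10 units of year noise, so the standardization stage has
  known per-nest offsets to recover.

What it does **not** emulate: humidity, spatial nest placement and
competition, logger gap patterns (gaps must be introduced explicitly),
weather fronts or heat waves (noise is stationary), and the video-derived
nature of swarm speed. Passing recovery tests therefore show the estimators
work when their structural assumptions hold at realistic noise levels — not
that field data meet those assumptions.

All generators draw from `numpy` Generators seeded by SeedSequence spawns
of a single user seed and are byte-reproducible.

## Problem sizes used in tests and the acceptance script

Recovery and calibration studies are sized to be informative yet quick on
one CPU: 100 seeds (tests) or 50 (script) for curve-peak recovery at the
study scale of 11 nests / 237 observations; 500 × 199 (tests) or 200 × 199
(script) replicates for RLRT calibration on 4 nests × 365 days; 50 / 20
seeds for change-point recovery at 3 nests × 40 observations; 200 ten-year
series for growth-model selection; 50 / 10 panels of 111 nests × 10 years
for effort standardization. The pipeline default of 199 RLRT simulations is
likewise a speed choice; production analyses should raise `n_sim_rlrt`
to 10,000.

## Known limitations

* The Laplace-approximate REML for binomial/Poisson smoothing-parameter
  selection is a PQL-flavored criterion; for very sparse binary data it can
  under-smooth relative to exact marginal likelihood.
* The RLRT grid maximization trades a small, shared bias in both models'
  restricted likelihoods for a large speed-up; calibration is preserved
  (verified empirically) but the reported statistic can differ from a
  continuous-optimum value by O(grid step²).
* Random-effect "EDF" and BIC comparisons treat the variance parameters as
  fixed at their REML estimates, the usual practical convention.
* The daytime parse induces a small exposure-correlated offset in *daytime*
  minima on a 30-min grid (the first sun-up sample of a strongly warming
  nest is already slightly warm), so daytime-minimum model selection can
  prefer a nest intercept even though pre-dawn minima are exactly common;
  full-day minima do not show this artifact.
* The change-point model assumes a sharp hockey-stick onset; applied to a
  smoothly rising curve it reads the onset low — the dedicated onset
  generator exists precisely to test the estimator under its own model.
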