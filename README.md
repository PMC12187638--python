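# thermoforage

Thermal-activity analysis for central-place-foraging ectotherms — built
around the kind of long-term field study where ant colonies occupy fixed
ground nests, their workers' activity outside the nest depends on substrate
surface temperature, and nest placement (sun vs shade) therefore determines
how many hours per day a colony can forage or defend itself.

The package turns three tidy CSV tables — hourly activity observations,
30-min nest surface-temperature logger series, and annual nest surveys —
into:

1. **Temperature-dependent performance curves.** Foraging traffic is a
   hurdle model: a logistic additive model for worker *presence* on the
   trail times a Poisson additive model for the *number* of workers once
   present, each with a penalized spline in surface temperature (k = 5) and
   a nest-identity random effect. The combined expectation
   `E[workers | T] = p(T) · μ(T)` is the performance curve. Defensive-swarm
   speed gets a Gaussian additive model. From each curve the package
   extracts the **peak temperature** (grid argmax), the **optimal window**
   (the contiguous interval where the curve stays ≥ 90 % of its maximum)
   and the **emergence window** (temperature extremes of observed activity,
   or where fitted presence crosses 0.5).
2. **A lower emergence threshold** via a hierarchical Bayesian change-point
   model: swarm speed is noise around zero below a nest-specific threshold
   τⱼ ~ N(μ_τ, σ_τ²) and rises linearly above it; the posterior is sampled
   with an ensemble MCMC sampler and reported with split-R̂/ESS diagnostics.
3. **Daily activity budgets.** Each logger day contributes
   0.5 h × #(30-min intervals with temperature inside a window), giving the
   inferred daily hours available for each activity.
4. **Among-nest variance tests.** Daily summaries are modeled by a cyclic
   seasonal smooth with no / random-intercept / random-intercept+slope nest
   effects, ranked by BIC and confirmed with a simulation-based restricted
   likelihood ratio test (parametric bootstrap of the REML statistic, which
   respects the boundary null).
5. **Compensation and growth.** Per-nest foraging effort is standardized by
   a log10 trail-count mixed model (effort at the population-mean nest
   size), regressed against available hours; per-nest annual size series
   are compared across intercept/linear/quadratic trends by AICc
   (ΔAICc ≤ 2 = supported) with t-values as effect sizes.

All of the statistics run on a purpose-built penalized-spline additive
model engine (`thermoforage.gam`): cubic regression splines parameterized
by knot values with a divided-difference curvature penalty, factor random
effects as ridge-penalized blocks, penalized IRLS for Gaussian / binomial /
Poisson families, and REML (Laplace-approximate outside the Gaussian
family) smoothing-parameter selection. Effective degrees of freedom are
trace-based and information criteria use the total EDF as dimension.

A first-class synthetic-data module generates every input with known ground
truth — shared overnight baseline temperatures (identical pre-dawn minima
across nests), nest-specific half-sine diurnal warming, AR(1) logger noise,
hurdle-process activity counts from a known unimodal curve, and annual
surveys under flat/linear/quadratic size trends — so every estimator has a
recovery test.

## Worked example

```python
import numpy as np
from thermoforage import (fit_hurdle, find_peak, optimal_window,
                          emergence_window, available_hours,
                          simulate_temperature_series, SimConfig)
from thermoforage.synthetic import simulate_hurdle_study

# a two-day (mid-summer + mid-winter) study: 11 nests, 237 hourly counts
obs, truth, profiles = simulate_hurdle_study(seed=1)

curve = fit_hurdle(obs, mode="primary")
peak = find_peak(curve)
lo, hi = optimal_window(curve, fraction=0.90)
em_lo, em_hi = emergence_window(obs)
print(f"peak {peak.peak_temp:.1f} C (truth {truth.true_peak():.1f}), "
      f"optimal {lo:.1f}-{hi:.1f} C, emergence {em_lo:.1f}-{em_hi:.1f} C")

# daily foraging hours for one sheltered nest
series = simulate_temperature_series(profiles[:1], SimConfig(seed=1))[0]
hours = available_hours(series, (em_lo, em_hi))
print(f"mean daily foraging hours: {hours['hours'].mean():.1f}")
```

Output:

```
peak 29.8 C (truth 29.7), optimal 27.6-32.0 C, emergence 11.6-41.3 C
mean daily foraging hours: 13.1
```

The fitted hurdle-curve peak lands within 0.1 °C of the generating curve's
true peak; the 90 % optimal window spans about 4.4 °C around it, while
workers are active over a ~30 °C emergence range. Averaged over two years,
this nest has about 13 h per day with its surface inside the emergence
window.

The same analyses are scriptable from the shell:

```bash
thermoforage simulate --seed 1 --out data/
thermoforage fit-curves --activity data/activity.csv --out windows.csv
thermoforage budget --loggers data/loggers.csv --lo 15.9 --hi 43.1 --out hours.csv
thermoforage run --config config.yaml      # full pipeline from YAML
```

## CSV schemas

| table    | columns |
|----------|---------|
| activity | `nest_id, datetime, surface_temp, worker_count, swarm_speed, time_of_day, light, wind, nest_size` (exactly one of `worker_count`/`swarm_speed` per row) |
| loggers  | `nest_id, timestamp, temp_C` (30-min cadence, ISO-8601) |
| surveys  | `nest_id, year, entrance_holes, n_foraging_trails, n_tree_trails, n_connection_trails` |

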