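"""Colony-level analyses: effort standardization, compensation, growth.

Foraging effort is indexed by the number of foraging and tree trails a nest
maintains. Because trail number scales with colony size, per-nest effort is
standardized by a Gaussian mixed model of log10 trail count on nest size
(random intercept and slope per nest, size centered at the population mean):
the back-transformed nest intercept is the trail count the nest would hold
at the average size, i.e. effort independent of size.

Compensation is probed by regressing mean nest size and standardized effort
on the hours available for foraging (summer apex and winter base of each
nest's seasonal hours trend): a compensating population would show no size
trend but more trails where hours are scarce.

Long-term growth is assessed per nest by comparing intercept-only, linear
and quadratic trends in annual entrance-hole counts with AICc (models within
two units of the best are also considered supported), with t-values as
effect sizes.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gam import RandomEffectSpec, SmoothSpec, fit_additive

GROWTH_MODELS = ("intercept", "linear", "quadratic")
#: minimum series length per model: AICc needs n - k - 1 > 0 with k the
#: number of regression coefficients
_MIN_YEARS = {"intercept": 3, "linear": 4, "quadratic": 5}


def standardize_effort(surveys: pd.DataFrame, include_connection: bool = False,
                       zero_policy: str = "drop") -> pd.DataFrame:
    """Size-independent per-nest foraging effort from annual surveys.

    Response is log10(foraging + tree trails) per nest-year (connection
    trails excluded by default); a Gaussian mixed model with a fixed size
    slope and per-nest random intercept and slope is fitted, and each nest's
    prediction at the population-mean size is back-transformed.

    ``zero_policy``: "drop" excludes zero-trail nest-years (with a warning),
    "add-one" uses log10(count + 1).
    """
    req = {"nest_id", "year", "entrance_holes", "n_foraging_trails", "n_tree_trails"}
    missing = req - set(surveys.columns)
    if missing:
        raise ValueError(f"survey table lacks columns {sorted(missing)}")
    df = surveys.copy()
    trails = df["n_foraging_trails"] + df["n_tree_trails"]
    if include_connection:
        trails = trails + df["n_connection_trails"]
    df["total_trails"] = trails

    n_nests = df["nest_id"].nunique()
    if n_nests < 10:
        raise ValueError(f"need >= 10 nests for effort standardization, got {n_nests}")
    years_per_nest = df.groupby("nest_id")["year"].nunique()
    if (years_per_nest < 3).any():
        raise ValueError("every nest needs >= 3 survey years")

    if zero_policy == "drop":
        n_zero = int((df["total_trails"] == 0).sum())
        if n_zero:
            _warnings.warn(f"dropping {n_zero} zero-trail nest-years from the "
                           "log10 response", stacklevel=2)
        df = df[df["total_trails"] > 0].copy()
        df["log10_trails"] = np.log10(df["total_trails"])
    elif zero_policy == "add-one":
        df["log10_trails"] = np.log10(df["total_trails"] + 1.0)
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")

    mean_size = float(df["entrance_holes"].mean())
    df["size_c"] = df["entrance_holes"] - mean_size
    fit = fit_additive(df, "log10_trails", parametric=("size_c",),
                       random_effect=RandomEffectSpec("nest_id", "intercept+slope",
                                                      "size_c"),
                       family="gaussian")
    b0 = float(fit.coefficients[0])
    re_term = fit.term("re(nest_id)")
    u0 = fit.coef_block("re(nest_id)")
    est = pd.DataFrame({
        "nest_id": re_term.levels,
        "standardized_trails": 10.0 ** (b0 + u0),
    })
    sizes = (surveys.groupby("nest_id")["entrance_holes"].mean()
             .rename("mean_size").reset_index())
    out = est.merge(sizes, on="nest_id").sort_values("nest_id").reset_index(drop=True)
    out.attrs["population_mean_size"] = mean_size
    return out


def seasonal_hours_summary(budget: pd.DataFrame, hours_col: str = "hours_emergence",
                           k: int = 8) -> pd.DataFrame:
    """Summer apex and winter base of each nest's seasonal daily-hours trend.

    Fits a cyclic smooth of daily hours on day-of-year per nest and reads the
    maximum (summer) and minimum (winter) of the fitted curve.
    """
    rows = []
    grid = pd.DataFrame({"doy": np.arange(1.0, 366.0)})
    for nest, grp in budget.groupby("nest_id", sort=True):
        d = grp.copy()
        d["doy"] = pd.DatetimeIndex(d["date"]).dayofyear.astype(float)
        fit = fit_additive(d.rename(columns={hours_col: "hours"}), "hours",
                           smooths=[SmoothSpec("doy", k=k, cyclic=True)],
                           family="gaussian")
        pred = fit.predict(grid)
        rows.append({"nest_id": nest,
                     "hours_summer": float(pred.max()),
                     "hours_winter": float(pred.min())})
    return pd.DataFrame(rows)


def compensation_test(effort: pd.DataFrame, hours: pd.DataFrame) -> pd.DataFrame:
    """Slopes of nest size and standardized effort against available hours.

    ``effort`` comes from :func:`standardize_effort`; ``hours`` from
    :func:`seasonal_hours_summary`. Returns one row per (season, response)
    with the OLS slope, its t-value and p-value; no decision rule is
    imposed. Degenerate regressions (constant hours) are flagged.
    """
    df = effort.merge(hours, on="nest_id")
    if len(df) < 4:
        raise ValueError(f"need >= 4 nests with effort and hours, got {len(df)}")
    rows = []
    for season, hcol in (("summer", "hours_summer"), ("winter", "hours_winter")):
        for resp, rcol in (("mean_size", "mean_size"),
                           ("standardized_trails", "standardized_trails")):
            x = df[hcol].to_numpy(dtype=float)
            y = df[rcol].to_numpy(dtype=float)
            if np.ptp(x) < 1e-12:
                rows.append({"season": season, "response": resp, "slope": np.nan,
                             "t": np.nan, "p": np.nan, "n": len(df),
                             "degenerate": True})
                continue
            res = stats.linregress(x, y)
            t = res.slope / res.stderr if res.stderr > 0 else np.inf * np.sign(res.slope)
            rows.append({"season": season, "response": resp,
                         "slope": float(res.slope), "t": float(t),
                         "p": float(res.pvalue), "n": len(df),
                         "degenerate": False})
    return pd.DataFrame(rows)


@dataclass
class GrowthFit:
    nest_id: str
    model: str
    aicc: float
    delta_aicc: float
    t_years: float | None
    t_years2: float | None
    supported: bool


def _ols_gaussian(t: np.ndarray, y: np.ndarray, degree: int):
    """OLS polynomial fit: returns (aicc, t-values per slope term)."""
    n = y.size
    X = np.vander(t, degree + 1, increasing=True)
    k = degree + 1  # regression coefficients
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    loglik = -0.5 * n * (np.log(2 * np.pi * max(rss, 1e-300) / n) + 1.0)
    aic = -2.0 * loglik + 2.0 * k
    if n - k - 1 <= 0:
        return None, None
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
    tvals = []
    if degree >= 1:
        dof = n - k
        sigma2 = rss / dof if dof > 0 else 0.0
        XtX_inv = np.linalg.inv(X.T @ X)
        for j in range(1, degree + 1):
            se = np.sqrt(max(sigma2 * XtX_inv[j, j], 0.0))
            if se == 0.0:
                tvals.append(float(np.sign(beta[j]) / np.finfo(float).eps))
            else:
                tvals.append(float(beta[j] / se))
    return float(aicc), tvals


def fit_growth_models(sizes: pd.DataFrame, nest_id: str | None = None,
                      drop_years: list[int] | None = None) -> pd.DataFrame:
    """Compare flat / linear / quadratic annual size trends for one nest.

    ``sizes`` needs columns year and entrance_holes. Years are centered at
    the first monitored year. Models whose AICc is undefined for the series
    length are omitted with a note; ``supported`` marks models within two
    AICc units of the best.
    """
    df = sizes.dropna(subset=["entrance_holes"]).sort_values("year")
    if drop_years:
        df = df[~df["year"].isin(drop_years)]
    years = df["year"].to_numpy(dtype=float)
    y = df["entrance_holes"].to_numpy(dtype=float)
    if np.unique(years).size != years.size:
        raise ValueError("duplicate years in growth series")
    n = y.size
    t = years - years.min()
    rows = []
    for model, degree in (("intercept", 0), ("linear", 1), ("quadratic", 2)):
        if n < _MIN_YEARS[model]:
            continue
        aicc, tvals = _ols_gaussian(t, y, degree)
        if aicc is None:
            continue
        rows.append({"nest_id": nest_id, "model": model, "aicc": aicc,
                     "t_years": tvals[0] if tvals else None,
                     "t_years2": tvals[1] if tvals and len(tvals) > 1 else None})
    if not rows:
        raise ValueError(f"series too short ({n} years) for any growth model")
    out = pd.DataFrame(rows)
    out["delta_aicc"] = out["aicc"] - out["aicc"].min()
    out["supported"] = out["delta_aicc"] <= 2.0
    return out.reset_index(drop=True)


def best_growth_model(sizes: pd.DataFrame) -> str:
    fits = fit_growth_models(sizes)
    return fits.loc[fits["delta_aicc"].idxmin(), "model"]
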