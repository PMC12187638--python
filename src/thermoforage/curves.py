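"""Thermal performance curves and their temperature summaries.

Foraging activity is modeled as a hurdle: a logistic additive model for
worker presence on the trail times a Poisson additive model for the number
of workers once present. The combined expectation p(T) * mu(T) is the
performance curve from which three summaries are extracted:

* the peak temperature (argmax on a grid over the observed range),
* the optimal window (maximal contiguous interval around the peak where the
  curve stays above a stated fraction of its maximum, 90% by default), and
* the emergence window (temperature extremes of observed activity, or the
  temperatures where fitted presence probability crosses one half).

Swarm (nest-defence) activity is a Gaussian additive model of swarm speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gam import AdditiveFit, FitError, RandomEffectSpec, SmoothSpec, fit_additive


@dataclass
class HurdleCurve:
    presence_fit: AdditiveFit
    count_fit: AdditiveFit
    mode: str  # "primary" | "adjusted"
    benchmark: dict = field(default_factory=dict)
    temp_range: tuple[float, float] = (0.0, 0.0)
    deviance_explained: float = 0.0

    def _newdata(self, temps: np.ndarray) -> pd.DataFrame:
        d = {"surface_temp": np.asarray(temps, dtype=float)}
        for key, val in self.benchmark.items():
            d[key] = val
        return pd.DataFrame(d)

    def presence(self, temps) -> np.ndarray:
        return self.presence_fit.predict(self._newdata(np.atleast_1d(temps)),
                                         re_action="zero")

    def conditional_mean(self, temps) -> np.ndarray:
        return self.count_fit.predict(self._newdata(np.atleast_1d(temps)),
                                      re_action="zero")

    def combined(self, temps) -> np.ndarray:
        """Expected workers: presence probability times conditional mean."""
        return self.presence(temps) * self.conditional_mean(temps)


@dataclass
class PeakResult:
    peak_temp: float
    peak_value: float
    at_boundary: bool


@dataclass
class PerformanceWindow:
    activity: str  # "foraging" | "swarm"
    peak_temp: float
    optimal_lo: float
    optimal_hi: float
    fraction: float
    emergence_lo: float
    emergence_hi: float
    method_emergence: str = "observed-range"

    def __post_init__(self) -> None:
        ok = (self.emergence_lo <= self.optimal_lo <= self.peak_temp
              <= self.optimal_hi <= self.emergence_hi)
        if not ok:
            raise ValueError(
                "window nesting violated: need emergence_lo <= optimal_lo <= "
                f"peak <= optimal_hi <= emergence_hi, got {self}")

    def to_dict(self) -> dict:
        return {
            "activity": self.activity, "peak_temp": self.peak_temp,
            "optimal_lo": self.optimal_lo, "optimal_hi": self.optimal_hi,
            "fraction": self.fraction, "emergence_lo": self.emergence_lo,
            "emergence_hi": self.emergence_hi,
            "method_emergence": self.method_emergence,
        }


def fit_hurdle(obs: pd.DataFrame, mode: str = "primary", k: int = 5) -> HurdleCurve:
    """Fit the two-part (presence x abundance) foraging curve.

    Primary mode uses surface temperature only (plus a nest random
    intercept); adjusted mode adds a parametric nest-size term and a
    time-of-day smooth, and benchmarks the curve to the median nest size at
    noon.
    """
    if mode not in ("primary", "adjusted"):
        raise ValueError(f"mode must be 'primary' or 'adjusted', got {mode!r}")
    df = obs.dropna(subset=["worker_count"]).copy()
    if len(df) < 30:
        raise ValueError(f"need >= 30 worker-count observations, got {len(df)}")
    df["present"] = (df["worker_count"] > 0).astype(float)
    n_pos = int(df["present"].sum())
    if n_pos == 0 or n_pos == len(df):
        raise FitError("cannot fit a hurdle: counts are all zero or all positive")

    smooths = [SmoothSpec("surface_temp", k=k)]
    parametric: tuple = ()
    benchmark: dict = {}
    if mode == "adjusted":
        smooths = smooths + [SmoothSpec("time_of_day", k=k)]
        parametric = ("nest_size",)
        benchmark = {"nest_size": float(df["nest_size"].median()), "time_of_day": 12.0}
    re = RandomEffectSpec("nest_id")

    presence_fit = fit_additive(df, "present", smooths=smooths,
                                parametric=parametric, random_effect=re,
                                family="binomial")
    pos = df[df["worker_count"] > 0].copy()
    pos["worker_count"] = pos["worker_count"].astype(int)
    count_fit = fit_additive(pos, "worker_count", smooths=smooths,
                             parametric=parametric, random_effect=re,
                             family="poisson")
    # joint deviance explained over the two hurdle parts
    dev = presence_fit.deviance + count_fit.deviance
    null = presence_fit.null_deviance + count_fit.null_deviance
    return HurdleCurve(presence_fit=presence_fit, count_fit=count_fit, mode=mode,
                       benchmark=benchmark,
                       temp_range=(float(df["surface_temp"].min()),
                                   float(df["surface_temp"].max())),
                       deviance_explained=float(1.0 - dev / null))


def fit_swarm_curve(obs: pd.DataFrame, mode: str = "primary", k: int = 5) -> AdditiveFit:
    """Gaussian additive model of swarm speed against nest surface temperature."""
    if mode not in ("primary", "adjusted"):
        raise ValueError(f"mode must be 'primary' or 'adjusted', got {mode!r}")
    df = obs.dropna(subset=["swarm_speed"]).copy()
    smooths = [SmoothSpec("surface_temp", k=k)]
    parametric: tuple = ()
    if mode == "adjusted":
        smooths = smooths + [SmoothSpec("time_of_day", k=k)]
        parametric = ("nest_size",)
    return fit_additive(df, "swarm_speed", smooths=smooths, parametric=parametric,
                        random_effect=RandomEffectSpec("nest_id"), family="gaussian")


def _curve_eval(curve, temps: np.ndarray, benchmark: dict | None = None) -> np.ndarray:
    if isinstance(curve, HurdleCurve):
        return curve.combined(temps)
    if hasattr(curve, "predict"):
        newdata = {"surface_temp": temps}
        for key, val in (benchmark or {}).items():
            newdata[key] = val
        return curve.predict(pd.DataFrame(newdata), re_action="zero")
    return np.asarray(curve(temps), dtype=float)  # plain callable T -> value


def _curve_range(curve, temp_range=None) -> tuple[float, float]:
    if temp_range is not None:
        return temp_range
    if isinstance(curve, HurdleCurve):
        return curve.temp_range
    if hasattr(curve, "design_"):
        for t in curve.design_.terms:
            if t.kind == "smooth" and t.basis.variable == "surface_temp":
                return t.basis.training_range
    raise ValueError("temperature range unknown; pass temp_range explicitly")


def find_peak(curve, grid_step: float = 0.1, temp_range=None,
              benchmark: dict | None = None) -> PeakResult:
    """Grid argmax of the performance curve over the observed temperature range.

    Ties break toward the lower temperature; a peak at either end of the
    range is flagged as a boundary peak.
    """
    lo, hi = _curve_range(curve, temp_range)
    grid = np.arange(lo, hi + grid_step / 2.0, grid_step)
    vals = _curve_eval(curve, grid, benchmark)
    if not np.all(np.isfinite(vals)):
        raise FitError("non-finite curve predictions on the evaluation grid")
    i = int(np.argmax(vals))  # argmax returns the first (lowest-T) maximizer
    return PeakResult(peak_temp=float(grid[i]), peak_value=float(vals[i]),
                      at_boundary=(i == 0 or i == grid.size - 1))


def optimal_window(curve, fraction: float = 0.90, grid_step: float = 0.1,
                   temp_range=None, benchmark: dict | None = None) -> tuple[float, float]:
    """Maximal contiguous interval around the peak with value >= fraction * peak."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    peak = find_peak(curve, grid_step=grid_step, temp_range=temp_range,
                     benchmark=benchmark)
    if peak.at_boundary:
        raise FitError("peak lies on the boundary of the observed range; "
                       "the optimal window is undefined")
    lo, hi = _curve_range(curve, temp_range)
    grid = np.arange(lo, hi + grid_step / 2.0, grid_step)
    vals = _curve_eval(curve, grid, benchmark)
    thresh = fraction * peak.peak_value
    i_peak = int(np.argmin(np.abs(grid - peak.peak_temp)))
    i_lo = i_peak
    while i_lo > 0 and vals[i_lo - 1] >= thresh:
        i_lo -= 1
    i_hi = i_peak
    while i_hi < grid.size - 1 and vals[i_hi + 1] >= thresh:
        i_hi += 1
    return float(grid[i_lo]), float(grid[i_hi])


def emergence_window(obs: pd.DataFrame, method: str = "observed-range",
                     curve: HurdleCurve | None = None,
                     grid_step: float = 0.1) -> tuple[float, float]:
    """Lower and upper temperatures bounding observed (or modeled) activity.

    ``observed-range``: min and max surface temperature over active
    observations (count > 0 or speed > 0). ``model-based``: temperatures at
    which the fitted presence probability crosses 0.5.
    """
    if method == "observed-range":
        active = np.zeros(len(obs), dtype=bool)
        if "worker_count" in obs:
            active |= obs["worker_count"].fillna(0).to_numpy() > 0
        if "swarm_speed" in obs:
            active |= obs["swarm_speed"].fillna(0).to_numpy() > 0
        if not active.any():
            raise ValueError("no active observations")
        temps = obs.loc[active, "surface_temp"].to_numpy(dtype=float)
        return float(temps.min()), float(temps.max())
    if method == "model-based":
        if curve is None:
            raise ValueError("model-based emergence needs a fitted HurdleCurve")
        lo, hi = curve.temp_range
        grid = np.arange(lo, hi + grid_step / 2.0, grid_step)
        p = curve.presence(grid)
        above = np.where(p >= 0.5)[0]
        if above.size == 0:
            raise FitError("fitted presence probability never reaches 0.5")
        return float(grid[above[0]]), float(grid[above[-1]])
    raise ValueError(f"unknown method {method!r}")


def upper_threshold_estimates(obs: pd.DataFrame) -> dict:
    """Liberal and conservative upper temperature thresholds from emergence flags.

    ``obs`` needs columns ``surface_temp`` and boolean ``emerged``. Liberal =
    the maximum temperature at which workers still emerged; conservative =
    the median temperature of non-emergence observations.
    """
    emerged = obs.loc[obs["emerged"].astype(bool), "surface_temp"]
    failed = obs.loc[~obs["emerged"].astype(bool), "surface_temp"]
    out: dict = {"liberal": None, "conservative": None, "consistent": None}
    if len(emerged):
        out["liberal"] = float(emerged.max())
    if len(failed):
        out["conservative"] = float(failed.median())
    if out["liberal"] is not None and out["conservative"] is not None:
        out["consistent"] = bool(out["liberal"] < out["conservative"])
    return out


def performance_window(obs: pd.DataFrame, curve, activity: str,
                       fraction: float = 0.90, grid_step: float = 0.1,
                       emergence_method: str = "observed-range") -> PerformanceWindow:
    """Assemble the full window summary for one activity type."""
    pk = find_peak(curve, grid_step=grid_step)
    opt_lo, opt_hi = optimal_window(curve, fraction=fraction, grid_step=grid_step)
    em_lo, em_hi = emergence_window(obs, method=emergence_method,
                                    curve=curve if isinstance(curve, HurdleCurve) else None,
                                    grid_step=grid_step)
    # observed-range bounds can sit a hair inside the grid ends; widen to nest
    em_lo = min(em_lo, opt_lo)
    em_hi = max(em_hi, opt_hi)
    return PerformanceWindow(activity=activity, peak_temp=pk.peak_temp,
                             optimal_lo=opt_lo, optimal_hi=opt_hi,
                             fraction=fraction, emergence_lo=em_lo,
                             emergence_hi=em_hi,
                             method_emergence=emergence_method)
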