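"""Daily summaries of logger series and available activity hours.

A nest's 30-min surface-temperature record is reduced to per-day daytime
minimum / maximum / range (the daytime parse applies to these summaries
only), and to the daily hours available for an activity: 0.5 h for every
observed interval whose temperature lies inside a performance window,
counted over the full 24 h by default (night temperatures fall below the
lower threshold and contribute zero naturally). Interval bounds are
inclusive at both ends because the thresholds are defined by observed
activity at those temperatures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import solar
from .synthetic import TemperatureSeries

daytime_mask = solar.daytime_mask


def _as_frame(series) -> pd.DataFrame:
    if isinstance(series, TemperatureSeries):
        return series.to_frame()
    df = pd.DataFrame(series)
    missing = {"nest_id", "timestamp", "temp_C"} - set(df.columns)
    if missing:
        raise ValueError(f"series table lacks columns {sorted(missing)}")
    return df


def expected_daytime_intervals(date, latitude: float, cadence_minutes: int = 30) -> int:
    """Number of cadence intervals with the sun up on one calendar day."""
    doy = pd.Timestamp(date).dayofyear
    sunrise, sunset = solar.sunrise_sunset_hours(doy, latitude)
    return int(np.ceil((sunset - sunrise) * 60.0 / cadence_minutes))


def summarize_daily(series, site_latitude: float, coverage_threshold: float = 0.9,
                    cadence_minutes: int = 30) -> pd.DataFrame:
    """Per-day daytime min / max / range with a completeness flag.

    A day is complete when the number of observed daytime intervals reaches
    ``coverage_threshold`` times the expected number for that date and
    latitude. Days with no daytime observations are absent from the output.
    """
    df = _as_frame(series)
    if df.empty:
        raise ValueError("series is empty")
    ts = pd.DatetimeIndex(df["timestamp"])
    mask = solar.daytime_mask(ts, site_latitude)
    day = df.loc[mask].assign(date=ts[mask].date)
    rows = []
    for (nest, date), grp in day.groupby(["nest_id", "date"], sort=True):
        temps = grp["temp_C"].to_numpy(dtype=float)
        n_obs = temps.size
        expected = expected_daytime_intervals(date, site_latitude, cadence_minutes)
        rows.append({
            "nest_id": nest, "date": pd.Timestamp(date),
            "n_intervals_observed": int(n_obs),
            "daytime_min": float(temps.min()),
            "daytime_max": float(temps.max()),
            "daytime_range": float(temps.max() - temps.min()),
            "complete": bool(n_obs >= coverage_threshold * expected),
        })
    return pd.DataFrame(rows)


def available_hours(series, window: tuple[float, float], site_latitude: float = -32.3,
                    scope: str = "full-day", coverage_threshold: float = 0.9,
                    cadence_minutes: int = 30) -> pd.DataFrame:
    """Daily hours with temperature inside [lo, hi] (inclusive).

    ``scope`` is "full-day" (default) or "daytime" to count sun-up intervals
    only. Hours are 0.5 x the count of qualifying observed intervals;
    missing intervals contribute nothing and the day carries a completeness
    flag from the daytime coverage rule.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError(f"window lower bound {lo} exceeds upper bound {hi}")
    if scope not in ("full-day", "daytime"):
        raise ValueError(f"scope must be 'full-day' or 'daytime', got {scope!r}")
    df = _as_frame(series)
    if df.empty:
        raise ValueError("series is empty")
    ts = pd.DatetimeIndex(df["timestamp"])
    if scope == "daytime":
        keep = solar.daytime_mask(ts, site_latitude)
        df = df.loc[keep]
        ts = ts[keep]
    completeness = summarize_daily(series, site_latitude,
                                   coverage_threshold=coverage_threshold,
                                   cadence_minutes=cadence_minutes)
    comp = {(r.nest_id, r.date.date()): r.complete for r in completeness.itertuples()}
    hours_per_interval = cadence_minutes / 60.0
    df = df.assign(date=ts.date,
                   inside=(df["temp_C"] >= lo) & (df["temp_C"] <= hi))
    rows = []
    for (nest, date), grp in df.groupby(["nest_id", "date"], sort=True):
        rows.append({
            "nest_id": nest, "date": pd.Timestamp(date),
            "hours": float(grp["inside"].sum() * hours_per_interval),
            "complete": bool(comp.get((nest, date), False)),
        })
    return pd.DataFrame(rows)


def activity_budget(series, emergence_window: tuple[float, float],
                    optimal_window: tuple[float, float], site_latitude: float = -32.3,
                    scope: str = "full-day", coverage_threshold: float = 0.9,
                    cadence_minutes: int = 30) -> pd.DataFrame:
    """Daily hours for both the emergence and optimal windows of one activity."""
    em = available_hours(series, emergence_window, site_latitude, scope,
                         coverage_threshold, cadence_minutes)
    op = available_hours(series, optimal_window, site_latitude, scope,
                         coverage_threshold, cadence_minutes)
    out = em.rename(columns={"hours": "hours_emergence"}).merge(
        op.rename(columns={"hours": "hours_optimal"})[["nest_id", "date", "hours_optimal"]],
        on=["nest_id", "date"])
    return out[["nest_id", "date", "hours_emergence", "hours_optimal", "complete"]]
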