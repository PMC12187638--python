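"""Solar position helpers shared by the simulator and the budget module.

Timestamps are treated as local standard time and the hour angle is computed
from the local clock (longitude-free approximation): solar noon is 12:00
local time. Declination uses the Cooper formula. This is accurate to well
under half an hour of day length at mid-latitudes, which is ample for
masking 30-min logger intervals to daytime.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: latitudes poleward of the polar circles see polar day/night; out of scope.
MAX_ABS_LATITUDE = 66.5


def _check_latitude(latitude: float) -> None:
    if not np.isfinite(latitude) or abs(latitude) > MAX_ABS_LATITUDE:
        raise ValueError(
            f"latitude must lie within +/-{MAX_ABS_LATITUDE} degrees, got {latitude!r}"
        )


def declination(day_of_year: np.ndarray) -> np.ndarray:
    """Solar declination (radians) for integer day of year."""
    return np.deg2rad(23.44) * np.sin(2.0 * np.pi * (284.0 + day_of_year) / 365.25)


def solar_elevation(timestamps: pd.DatetimeIndex, latitude: float) -> np.ndarray:
    """Solar elevation angle in radians at each local-clock timestamp."""
    _check_latitude(latitude)
    ts = pd.DatetimeIndex(timestamps)
    doy = ts.dayofyear.to_numpy(dtype=float)
    hours = (
        ts.hour.to_numpy(dtype=float)
        + ts.minute.to_numpy(dtype=float) / 60.0
        + ts.second.to_numpy(dtype=float) / 3600.0
    )
    dec = declination(doy)
    lat = np.deg2rad(latitude)
    hour_angle = np.deg2rad(15.0 * (hours - 12.0))
    sin_elev = np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.cos(hour_angle)
    return np.arcsin(np.clip(sin_elev, -1.0, 1.0))


def daytime_mask(timestamps: pd.DatetimeIndex, latitude: float) -> np.ndarray:
    """Boolean mask, True where the sun is above the horizon."""
    return solar_elevation(timestamps, latitude) > 0.0


def sunrise_sunset_hours(day_of_year: float, latitude: float) -> tuple[float, float]:
    """Local-clock sunrise and sunset hours for one day.

    Returns (sunrise, sunset) as fractional hours around local solar noon
    (12:00). Raises for polar latitudes (enforced by the caller contract).
    """
    _check_latitude(latitude)
    dec = declination(np.asarray(float(day_of_year)))
    lat = np.deg2rad(latitude)
    cos_h = -np.tan(lat) * np.tan(dec)
    cos_h = float(np.clip(cos_h, -1.0, 1.0))
    half_day = np.rad2deg(np.arccos(cos_h)) / 15.0  # hours
    return 12.0 - half_day, 12.0 + half_day
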