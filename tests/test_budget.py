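import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoforage.budget import (activity_budget, available_hours,
                                 summarize_daily)

LAT = -32.3


def day_frame(temps, nest="n1", date="2019-03-01"):
    start = pd.Timestamp(date)
    ts = pd.date_range(start, periods=len(temps), freq="30min")
    return pd.DataFrame({"nest_id": nest, "timestamp": ts, "temp_C": temps})


class TestSummarizeDaily:
    def test_constant_day_zero_range(self):
        df = day_frame([20.0] * 48)
        rec = summarize_daily(df, LAT).iloc[0]
        assert rec.daytime_min == rec.daytime_max == 20.0
        assert rec.daytime_range == 0.0
        assert rec.complete

    def test_half_missing_day_incomplete(self):
        df = day_frame([20.0] * 48)
        thin = df.iloc[::4]  # keep a quarter of intervals
        rec = summarize_daily(thin, LAT, coverage_threshold=0.9).iloc[0]
        assert not rec.complete

    def test_min_max_match_brute_force_scan(self, noisefree_series):
        series, cfg, _ = noisefree_series
        from thermoforage.solar import daytime_mask
        s = series[1]
        recs = summarize_daily(s, cfg.site_latitude)
        f = s.to_frame()
        mask = daytime_mask(pd.DatetimeIndex(f["timestamp"]), cfg.site_latitude)
        f = f[mask]
        for rec in recs.itertuples():
            vals = f[f["timestamp"].dt.date == rec.date.date()]["temp_C"]
            assert rec.daytime_min == vals.min()
            assert rec.daytime_max == vals.max()

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_daily(day_frame([]), LAT)


class TestAvailableHours:
    def test_saturated_day_gives_24_hours(self):
        df = day_frame([25.0] * 48)
        out = available_hours(df, (20.0, 30.0), LAT)
        assert out.iloc[0].hours == 24.0

    def test_no_interval_inside_gives_zero(self):
        df = day_frame([5.0] * 48)
        out = available_hours(df, (20.0, 30.0), LAT)
        assert out.iloc[0].hours == 0.0

    def test_inclusive_bounds(self):
        df = day_frame([20.0, 30.0, 19.99, 30.01] + [0.0] * 44)
        out = available_hours(df, (20.0, 30.0), LAT)
        assert out.iloc[0].hours == 1.0  # exactly the two boundary readings

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            available_hours(day_frame([20.0] * 4), (30.0, 20.0), LAT)

    def test_counting_matches_brute_force_loop(self, rng):
        """available_hours equals an explicit per-interval loop."""
        for _ in range(50):
            temps = rng.uniform(-5, 50, 48)
            lo = float(rng.uniform(-5, 45))
            hi = lo + float(rng.uniform(0, 20))
            df = day_frame(temps)
            out = available_hours(df, (lo, hi), LAT)
            brute = 0
            for t in temps:
                if lo <= t <= hi:
                    brute += 1
            assert out.iloc[0].hours == pytest.approx(brute * 0.5)

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0, 10), st.floats(0, 10))
    def test_widening_window_never_decreases_hours(self, pad_lo, pad_hi):
        rng = np.random.default_rng(17)
        temps = rng.uniform(0, 45, 96)
        df = day_frame(temps)
        base = available_hours(df, (15.0, 30.0), LAT)["hours"]
        wide = available_hours(df, (15.0 - pad_lo, 30.0 + pad_hi), LAT)["hours"]
        assert np.all(wide.to_numpy() >= base.to_numpy())

    def test_hours_are_half_hour_multiples(self, noisefree_series):
        series, cfg, _ = noisefree_series
        out = available_hours(series[0], (10.0, 25.0), cfg.site_latitude)
        assert np.allclose(out["hours"] * 2, np.round(out["hours"] * 2))


class TestActivityBudget:
    def test_nested_windows_nest_hours(self, noisefree_series):
        series, cfg, _ = noisefree_series
        b = activity_budget(series[1], (10.0, 40.0), (20.0, 30.0),
                            cfg.site_latitude)
        assert np.all(b["hours_optimal"] <= b["hours_emergence"])
        assert np.all((b["hours_emergence"] >= 0) & (b["hours_emergence"] <= 24))

    def test_halfsine_day_matches_analytic_hours(self):
        """On a noise-free half-sine day the interval count matches the
        analytic time spent inside the window to within one interval."""
        from thermoforage.synthetic import (NestProfile, SimConfig,
                                            simulate_temperature_series)
        cfg = SimConfig(noise_sd=0.0, date_range=("2019-01-10", "2019-01-11"))
        prof = NestProfile("x", 12.0, seasonal_amplitude=0.0)
        s = simulate_temperature_series([prof], cfg)[0]
        from thermoforage.solar import sunrise_sunset_hours
        doy = pd.Timestamp("2019-01-10").dayofyear
        sunrise, sunset = sunrise_sunset_hours(doy, cfg.site_latitude)
        base = s.temps.min()
        lo = base + 6.0  # half the bump amplitude
        out = available_hours(s, (lo, 60.0), cfg.site_latitude)
        # bump exceeds A/2 over the middle 2/3 of daylight (arcsin(1/2))
        daylen = sunset - sunrise
        analytic = daylen * (1.0 - 2.0 / np.pi * np.arcsin(0.5))
        assert abs(out.iloc[0].hours - analytic) <= 0.5
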