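import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoforage.curves import (emergence_window, find_peak, fit_hurdle,
                                 optimal_window, performance_window,
                                 upper_threshold_estimates)
from thermoforage.gam import FitError


def gaussian_curve(peak=30.0, sd=3.0):
    return lambda T: np.exp(-0.5 * ((np.asarray(T) - peak) / sd) ** 2)


class TestFindPeak:
    def test_symmetric_curve_peak_recovered(self):
        pk = find_peak(gaussian_curve(30.0), temp_range=(20.0, 40.0))
        assert abs(pk.peak_temp - 30.0) <= 0.1
        assert not pk.at_boundary

    def test_monotone_curve_flagged_as_boundary(self):
        pk = find_peak(lambda T: np.asarray(T, float), temp_range=(10.0, 35.0))
        assert pk.at_boundary and pk.peak_temp == pytest.approx(35.0)

    def test_grid_argmax_matches_finer_grid(self, hurdle_fit):
        hc, _ = hurdle_fit
        coarse = find_peak(hc, grid_step=0.1)
        fine = find_peak(hc, grid_step=0.01)
        assert abs(coarse.peak_temp - fine.peak_temp) <= 0.1

    def test_ties_break_to_lower_temperature(self):
        pk = find_peak(lambda T: np.ones_like(np.asarray(T, float)),
                       temp_range=(10.0, 20.0))
        assert pk.peak_temp == pytest.approx(10.0)


class TestOptimalWindow:
    def test_gaussian_closed_form_half_width(self):
        """For a Gaussian curve of sd 3, the 90% window half-width is
        3*sqrt(-2 ln 0.9)."""
        lo, hi = optimal_window(gaussian_curve(30.0, 3.0), fraction=0.9,
                                temp_range=(20.0, 40.0))
        expected = 3.0 * np.sqrt(-2.0 * np.log(0.9))
        assert abs((hi - lo) / 2.0 - expected) <= 0.1

    def test_fraction_one_gives_degenerate_window(self):
        lo, hi = optimal_window(gaussian_curve(30.0), fraction=1.0,
                                temp_range=(20.0, 40.0))
        assert hi - lo <= 0.2

    def test_smaller_fraction_widens_window(self, hurdle_fit):
        hc, _ = hurdle_fit
        w9 = optimal_window(hc, fraction=0.9)
        w5 = optimal_window(hc, fraction=0.5)
        assert w5[0] <= w9[0] and w5[1] >= w9[1]

    def test_boundary_peak_refuses_window(self):
        with pytest.raises(FitError, match="boundary"):
            optimal_window(lambda T: np.asarray(T, float), temp_range=(0.0, 10.0))

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            optimal_window(gaussian_curve(), fraction=1.5, temp_range=(20, 40))


class TestEmergenceWindow:
    def test_single_active_observation(self):
        obs = pd.DataFrame({"surface_temp": [20.0, 25.0],
                            "worker_count": [3, 0]})
        assert emergence_window(obs) == (20.0, 20.0)

    def test_printed_style_range(self):
        temps = [15.9, 20.0, 30.0, 43.1]
        obs = pd.DataFrame({"surface_temp": temps, "worker_count": [1, 5, 9, 2]})
        assert emergence_window(obs) == (15.9, 43.1)

    def test_no_active_observations(self):
        obs = pd.DataFrame({"surface_temp": [20.0], "worker_count": [0]})
        with pytest.raises(ValueError, match="active"):
            emergence_window(obs)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(-5, 55), st.integers(0, 30)),
                    min_size=1, max_size=60))
    def test_observed_range_equals_brute_force(self, rows):
        obs = pd.DataFrame(rows, columns=["surface_temp", "worker_count"])
        active = [t for t, c in rows if c > 0]
        if not active:
            with pytest.raises(ValueError):
                emergence_window(obs)
        else:
            lo, hi = emergence_window(obs)
            assert lo == min(active) and hi == max(active)

    def test_model_based_crosses_half(self, hurdle_fit):
        hc, curve = hurdle_fit
        lo, hi = emergence_window(pd.DataFrame(), method="model-based", curve=hc)
        assert lo < curve.peak_temp < hi


class TestUpperThresholds:
    def test_median_of_three(self):
        obs = pd.DataFrame({"surface_temp": [37.3, 42.2, 47.4, 40.0],
                            "emerged": [False, False, False, True]})
        est = upper_threshold_estimates(obs)
        assert est["conservative"] == 42.2
        assert est["liberal"] == 40.0

    def test_consistency_flag(self):
        obs = pd.DataFrame({"surface_temp": [30.0, 31.0, 40.0, 41.0],
                            "emerged": [True, True, False, False]})
        est = upper_threshold_estimates(obs)
        assert est["liberal"] < est["conservative"] and est["consistent"]

    def test_empty_category_unavailable(self):
        obs = pd.DataFrame({"surface_temp": [30.0], "emerged": [True]})
        est = upper_threshold_estimates(obs)
        assert est["liberal"] == 30.0 and est["conservative"] is None

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(10, 50), min_size=1, max_size=25))
    def test_conservative_equals_sort_oracle(self, temps):
        obs = pd.DataFrame({"surface_temp": temps, "emerged": False})
        est = upper_threshold_estimates(obs)
        srt = sorted(temps)
        n = len(srt)
        oracle = (srt[n // 2] if n % 2 else 0.5 * (srt[n // 2 - 1] + srt[n // 2]))
        assert est["conservative"] == pytest.approx(oracle)


class TestHurdle:
    def test_recovers_true_peak(self, hurdle_fit):
        hc, curve = hurdle_fit
        pk = find_peak(hc)
        assert abs(pk.peak_temp - curve.true_peak()) <= 1.0

    def test_degenerate_counts_rejected(self):
        obs = pd.DataFrame({
            "nest_id": ["a"] * 35, "surface_temp": 25.0,
            "worker_count": 3, "nest_size": 30, "time_of_day": 12.0})
        with pytest.raises(FitError, match="hurdle"):
            fit_hurdle(obs)

    def test_too_few_observations_rejected(self):
        obs = pd.DataFrame({"nest_id": ["a"] * 10, "surface_temp": 25.0,
                            "worker_count": [0, 1] * 5})
        with pytest.raises(ValueError, match=">= 30"):
            fit_hurdle(obs)

    def test_combined_below_conditional_mean(self, hurdle_fit):
        hc, _ = hurdle_fit
        grid = np.linspace(*hc.temp_range, 100)
        assert np.all(hc.combined(grid) <= hc.conditional_mean(grid) + 1e-9)
        assert np.all(hc.combined(grid) >= 0.0)

    def test_primary_and_adjusted_peaks_close(self, hurdle_study):
        """Without confounders the two modes give nearly the same curve."""
        obs, curve, _ = hurdle_study
        primary = fit_hurdle(obs, "primary")
        adjusted = fit_hurdle(obs, "adjusted")
        p1 = find_peak(primary).peak_temp
        p2 = find_peak(adjusted).peak_temp
        assert abs(p1 - p2) < 1.0

    def test_window_nesting_invariant(self, hurdle_study, hurdle_fit):
        obs, _, _ = hurdle_study
        hc, _ = hurdle_fit
        w = performance_window(obs, hc, "foraging")
        assert (w.emergence_lo <= w.optimal_lo <= w.peak_temp
                <= w.optimal_hi <= w.emergence_hi)
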