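import numpy as np
import pandas as pd
import pytest

from thermoforage.synthetic import (GrowthTrend, NestProfile, SimConfig,
                                    TrueCurveSpec, baseline_temperature,
                                    default_study_profiles, simulate_activity,
                                    simulate_hurdle_study, simulate_surveys,
                                    simulate_swarm_onset,
                                    simulate_temperature_series,
                                    solar_noon_temperature)


class TestTemperatureSeries:
    def test_zero_amplitude_series_is_baseline_everywhere(self):
        cfg = SimConfig(noise_sd=0.0, date_range=("2019-01-01", "2019-02-01"))
        s = simulate_temperature_series([NestProfile("flat", 0.0)], cfg)[0]
        assert np.allclose(s.temps, baseline_temperature(cfg, s.timestamps))

    def test_noisefree_daily_minima_identical_across_nests(self, noisefree_series):
        series, cfg, _ = noisefree_series
        mins = []
        for s in series:
            f = s.to_frame()
            mins.append(f.groupby(f["timestamp"].dt.date)["temp_C"].min())
        assert np.allclose(mins[0], mins[1])

    def test_daily_ranges_ordered_by_exposure(self, noisefree_series):
        series, cfg, profiles = noisefree_series
        rngs = []
        for s in series:
            f = s.to_frame()
            g = f.groupby(f["timestamp"].dt.date)["temp_C"]
            rngs.append((g.max() - g.min()).to_numpy())
        shaded, exposed = rngs
        assert np.all(exposed >= shaded - 1e-9)

    def test_solar_noon_matches_closed_form(self):
        cfg = SimConfig(noise_sd=0.0)
        prof = NestProfile("x", 10.0, seasonal_amplitude=0.0)
        doy = pd.Timestamp("2019-01-20").dayofyear
        expected = (cfg.baseline_mean + cfg.baseline_seasonal_amplitude
                    * np.cos(2 * np.pi * (doy - 15) / 365.25) + 10.0)
        assert abs(solar_noon_temperature(prof, cfg, "2019-01-20") - expected) < 1e-9

    def test_discrete_daily_max_near_noon_value(self):
        cfg = SimConfig(noise_sd=0.0, date_range=("2019-01-10", "2019-01-12"))
        prof = NestProfile("x", 10.0, seasonal_amplitude=0.0)
        s = simulate_temperature_series([prof], cfg)[0]
        f = s.to_frame()
        day = f[f["timestamp"].dt.date == pd.Timestamp("2019-01-10").date()]
        noon = solar_noon_temperature(prof, cfg, "2019-01-10")
        assert day["temp_C"].max() <= noon + 1e-9
        assert noon - day["temp_C"].max() < 0.1

    def test_reproducible_under_seed(self):
        cfg = SimConfig(noise_sd=1.0, seed=99, date_range=("2019-01-01", "2019-01-20"))
        profs = [NestProfile("a", 8.0)]
        s1 = simulate_temperature_series(profs, cfg)[0]
        s2 = simulate_temperature_series(profs, cfg)[0]
        assert np.array_equal(s1.temps, s2.temps)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_temperature_series([], SimConfig())
        with pytest.raises(ValueError, match="degenerate"):
            SimConfig(date_range=("2019-01-01", "2019-01-01"))
        with pytest.raises(ValueError):
            SimConfig(cadence_minutes=7)
        with pytest.raises(ValueError):
            SimConfig(noise_autocorrelation=1.0)


class TestActivity:
    def test_counts_vanish_far_below_presence_midpoint(self):
        curve = TrueCurveSpec()
        assert curve.presence_prob(-5.0) < 1e-4

    def test_mc_mean_count_at_peak_matches_analytic(self):
        """Monte-Carlo mean of the hurdle draw equals presence x rate."""
        curve = TrueCurveSpec()
        rng = np.random.default_rng(0)
        n = 10_000
        T = curve.peak_temp
        p = float(curve.presence_prob(T))
        mu = float(curve.conditional_mean(T))
        draws = np.where(rng.random(n) < p, rng.poisson(mu, n), 0)
        analytic = p * mu
        se = np.sqrt((p * (mu + mu**2) - (p * mu) ** 2) / n)
        assert abs(draws.mean() - analytic) < 3 * se

    def test_activity_deterministic_under_seed(self, noisefree_series):
        series, cfg, profiles = noisefree_series
        a = simulate_activity(series, TrueCurveSpec(), profiles, seed=5, config=cfg)
        b = simulate_activity(series, TrueCurveSpec(), profiles, seed=5, config=cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_schedule_outside_series_rejected(self, noisefree_series):
        series, cfg, profiles = noisefree_series
        bad = pd.DatetimeIndex([pd.Timestamp("2030-01-01 12:00")])
        with pytest.raises(ValueError, match="schedule"):
            simulate_activity(series, TrueCurveSpec(), profiles, sampling=bad,
                              config=cfg)

    def test_curve_spec_invariants(self):
        with pytest.raises(ValueError):
            TrueCurveSpec(curve_width=0.0)
        with pytest.raises(ValueError):
            TrueCurveSpec(presence_midpoints=(35.0, 43.0))  # peak below lower

    def test_study_has_requested_shape(self, hurdle_study):
        obs, curve, profiles = hurdle_study
        assert len(obs) == 237
        assert obs["nest_id"].nunique() == 11
        assert ((obs["worker_count"] == 0).any()
                and (obs["worker_count"] > 0).any())


class TestSurveys:
    def test_flat_trend_no_noise_constant_size(self):
        profs = default_study_profiles(3)
        sv = simulate_surveys(profs, GrowthTrend("flat", noise_sd=0.0), 5)
        for _, g in sv.groupby("nest_id"):
            assert g["entrance_holes"].nunique() == 1

    def test_linear_trend_arithmetic(self):
        profs = [NestProfile("a", 5.0, size_holes=40)]
        sv = simulate_surveys(profs, GrowthTrend("linear", slope=-3.0, noise_sd=0.0), 10)
        holes = sv["entrance_holes"].to_numpy()
        assert holes[-1] == holes[0] - 27

    def test_years_minimum(self):
        with pytest.raises(ValueError):
            simulate_surveys(default_study_profiles(3), GrowthTrend("flat"), 2)

    def test_swarm_onset_truth_columns(self):
        sw = simulate_swarm_onset(seed=1, n_nests=4)
        assert sw["nest_id"].nunique() == 4
        assert sw.groupby("nest_id")["true_threshold"].nunique().eq(1).all()
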