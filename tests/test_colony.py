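import numpy as np
import pandas as pd
import pytest

from thermoforage.colony import (compensation_test, fit_growth_models,
                                 seasonal_hours_summary, standardize_effort)
from thermoforage.synthetic import (GrowthTrend, NestProfile, simulate_surveys)


def make_profiles(n, rng, prop_sd=0.2):
    return [NestProfile(f"N{i:03d}", 10.0,
                        size_holes=int(np.clip(np.round(rng.normal(32, 14)), 6, 58)),
                        trail_propensity=float(rng.normal(0, prop_sd)))
            for i in range(n)]


class TestStandardizeEffort:
    def test_identical_nests_get_equal_estimates(self):
        profs = [NestProfile(f"N{i}", 10.0, size_holes=30, trail_propensity=0.0)
                 for i in range(12)]
        sv = simulate_surveys(profs, GrowthTrend("flat", noise_sd=0.0), 5, seed=0)
        # force identical trail counts
        sv["n_foraging_trails"] = 2
        sv["n_tree_trails"] = 2
        eff = standardize_effort(sv)
        assert np.ptp(eff["standardized_trails"].to_numpy()) < 1e-8

    def test_doubling_counts_doubles_estimates(self, rng):
        profs = make_profiles(15, rng)
        sv = simulate_surveys(profs, GrowthTrend("flat"), 6, seed=1)
        sv = sv[sv["n_foraging_trails"] + sv["n_tree_trails"] > 0]
        eff1 = standardize_effort(sv)
        sv2 = sv.assign(n_foraging_trails=2 * sv["n_foraging_trails"],
                        n_tree_trails=2 * sv["n_tree_trails"])
        eff2 = standardize_effort(sv2)
        ratio = eff2["standardized_trails"] / eff1["standardized_trails"]
        assert np.allclose(ratio, 2.0, atol=1e-6)

    def test_recovers_propensity_ranks(self, rng):
        from scipy.stats import spearmanr
        profs = make_profiles(60, rng)
        sv = simulate_surveys(profs, GrowthTrend("flat"), 8, seed=2)
        eff = standardize_effort(sv).set_index("nest_id")
        truth = pd.Series({p.nest_id: p.trail_propensity for p in profs})
        rho = spearmanr(eff.loc[truth.index, "standardized_trails"], truth).statistic
        assert rho >= 0.9

    def test_invariant_to_year_reordering(self, rng):
        profs = make_profiles(12, rng)
        sv = simulate_surveys(profs, GrowthTrend("flat"), 5, seed=3)
        shuffled = sv.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = standardize_effort(sv)
        b = standardize_effort(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_nests_rejected(self, rng):
        profs = make_profiles(5, rng)
        sv = simulate_surveys(profs, GrowthTrend("flat"), 5, seed=4)
        with pytest.raises(ValueError, match="10 nests"):
            standardize_effort(sv)


class TestCompensation:
    @staticmethod
    def effort_frame(hours, trails, sizes):
        eff = pd.DataFrame({"nest_id": [f"N{i}" for i in range(len(hours))],
                            "standardized_trails": trails, "mean_size": sizes})
        hrs = pd.DataFrame({"nest_id": eff["nest_id"],
                            "hours_summer": hours,
                            "hours_winter": np.asarray(hours) * 0.3})
        return eff, hrs

    def test_recovers_negative_coupling(self, rng):
        hours = np.linspace(2, 14, 8)
        trails = 10 - 0.5 * hours + rng.normal(0, 0.1, 8)
        sizes = np.full(8, 30.0)
        eff, hrs = self.effort_frame(hours, trails, sizes)
        rep = compensation_test(eff, hrs)
        row = rep[(rep.season == "summer") & (rep.response == "standardized_trails")]
        assert row.iloc[0]["slope"] < 0

    def test_recovers_positive_size_trend(self, rng):
        hours = np.linspace(2, 14, 8)
        sizes = 10 + 2.0 * hours + rng.normal(0, 1.0, 8)
        trails = np.full(8, 4.0)
        eff, hrs = self.effort_frame(hours, trails, sizes)
        rep = compensation_test(eff, hrs)
        row = rep[(rep.season == "summer") & (rep.response == "mean_size")]
        assert row.iloc[0]["slope"] > 0

    def test_constant_hours_degenerate(self):
        eff, hrs = self.effort_frame([5.0] * 6, np.arange(6.0), np.arange(6.0))
        rep = compensation_test(eff, hrs)
        assert rep["degenerate"].all()

    def test_too_few_nests(self):
        eff, hrs = self.effort_frame([1.0, 2.0, 3.0], [1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match=">= 4"):
            compensation_test(eff, hrs)


class TestGrowthModels:
    def test_constant_series_prefers_intercept(self):
        df = pd.DataFrame({"year": 2015 + np.arange(8), "entrance_holes": 30})
        fits = fit_growth_models(df)
        best = fits.loc[fits["delta_aicc"].idxmin(), "model"]
        assert best == "intercept"

    def test_exact_line_gives_linear_best_with_huge_t(self):
        df = pd.DataFrame({"year": 2000 + np.arange(5),
                           "entrance_holes": [10, 8, 6, 4, 2]})
        fits = fit_growth_models(df).set_index("model")
        assert fits.loc["linear", "delta_aicc"] == 0.0
        assert fits.loc["linear", "t_years"] < -1e6  # se collapses to zero

    def test_aicc_exceeds_aic_and_gap_shrinks_with_n(self, rng):
        gaps = []
        for n in (6, 10, 20):
            y = 30 + rng.normal(0, 3, n)
            df = pd.DataFrame({"year": 2000 + np.arange(n), "entrance_holes": y})
            fits = fit_growth_models(df).set_index("model")
            k = 2  # linear regression coefficients
            gaps.append(2.0 * k * (k + 1) / (n - k - 1))
        assert gaps[0] > gaps[1] > gaps[2] > 0

    def test_short_series_omits_models(self):
        df = pd.DataFrame({"year": [2015, 2016, 2017, 2018],
                           "entrance_holes": [30, 31, 29, 30]})
        fits = fit_growth_models(df)
        assert set(fits["model"]) == {"intercept", "linear"}

    def test_drop_years_variant(self):
        years = 2015 + np.arange(11)
        sizes = np.concatenate([[60.0], 30 - 2.5 * np.arange(10)])
        df = pd.DataFrame({"year": years, "entrance_holes": sizes})
        full = fit_growth_models(df).set_index("model")
        dropped = fit_growth_models(df, drop_years=[2015]).set_index("model")
        # removing the outlier first year strengthens the linear trend
        assert dropped.loc["linear", "delta_aicc"] == 0.0
        assert abs(dropped.loc["linear", "t_years"]) > abs(full.loc["linear", "t_years"])

    def test_supported_flag_uses_two_unit_rule(self, rng):
        df = pd.DataFrame({"year": 2015 + np.arange(10),
                           "entrance_holes": 30 + rng.normal(0, 3, 10)})
        fits = fit_growth_models(df)
        assert (fits["supported"] == (fits["delta_aicc"] <= 2.0)).all()


def test_seasonal_hours_summary_orders_apex_base(noisefree_series):
    from thermoforage.budget import activity_budget
    series, cfg, _ = noisefree_series
    parts = [activity_budget(s, (10.0, 45.0), (20.0, 32.0), cfg.site_latitude)
             for s in series]
    hrs = seasonal_hours_summary(pd.concat(parts, ignore_index=True))
    assert (hrs["hours_summer"] >= hrs["hours_winter"]).all()
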