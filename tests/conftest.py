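import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from thermoforage.curves import fit_hurdle  # noqa: E402
from thermoforage.synthetic import (NestProfile, SimConfig,  # noqa: E402
                                    simulate_hurdle_study,
                                    simulate_temperature_series)


@pytest.fixture(scope="session")
def hurdle_study():
    """One simulated two-day foraging study of 11 nests / 237 observations."""
    obs, curve, profiles = simulate_hurdle_study(seed=11)
    return obs, curve, profiles


@pytest.fixture(scope="session")
def hurdle_fit(hurdle_study):
    obs, curve, profiles = hurdle_study
    return fit_hurdle(obs, "primary"), curve


@pytest.fixture(scope="session")
def noisefree_series():
    """Two noise-free logger series with contrasting exposure amplitudes."""
    profiles = [NestProfile("shaded", 6.0, seasonal_amplitude=4.0),
                NestProfile("exposed", 18.0, seasonal_amplitude=4.0)]
    cfg = SimConfig(noise_sd=0.0, date_range=("2019-01-01", "2019-06-30"))
    return simulate_temperature_series(profiles, cfg), cfg, profiles


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def daily_values():
    """Per-nest daily values with distinct nest offsets (seasonal + offset)."""
    from thermoforage.variance import seasonal_index
    rng = np.random.default_rng(7)
    dates = pd.date_range("2019-01-01", "2019-12-31", freq="D")
    rows = []
    for i, nid in enumerate(["A", "B", "C", "D"]):
        mu = 12.0 + 5.0 * seasonal_index(dates) + 1.5 * i
        rows.append(pd.DataFrame({"nest_id": nid, "date": dates,
                                  "value": mu + rng.normal(0, 1.5, len(dates))}))
    return pd.concat(rows, ignore_index=True)
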