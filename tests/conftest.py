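import numpy as np
import pandas as pd
import pytest

from irripls import SimConfig, make_training_scenario, train_pipeline


@pytest.fixture(scope="session")
def scenario():
    """Default-noise synthetic season (120 days)."""
    return make_training_scenario(SimConfig(n_days=120, seed=3))


@pytest.fixture(scope="session")
def noise_free_scenario():
    return make_training_scenario(SimConfig(n_days=120, seed=5, noise_scale=0.0))


@pytest.fixture(scope="session")
def fitted(scenario):
    return train_pipeline(scenario.daily)


def make_daily(n_days=10, seed=0, start="2021-06-01"):
    """Small deterministic daily table with all canonical columns."""
    rng = np.random.default_rng(seed)
    idx = pd.date_range(start, periods=n_days, freq="D", name="date")
    df = pd.DataFrame(
        {
            "rh_mean": rng.uniform(40, 90, n_days),
            "rh_min": rng.uniform(20, 40, n_days),
            "rh_max": rng.uniform(90, 100, n_days),
            "t_mean": rng.uniform(15, 25, n_days),
            "t_min": rng.uniform(8, 15, n_days),
            "t_max": rng.uniform(25, 32, n_days),
            "dew_mean": rng.uniform(5, 15, n_days),
            "wind_dir": rng.uniform(0, 360, n_days),
            "wind_mean": rng.uniform(0, 20, n_days),
            "wind_gust": rng.uniform(20, 40, n_days),
            "rain_mm": rng.gamma(1.0, 2.0, n_days) * (rng.random(n_days) < 0.4),
            "solar_mean": rng.uniform(100, 300, n_days),
            "sm30": rng.uniform(8, 16, n_days),
            "sm60": rng.uniform(12, 20, n_days),
            "sm90": rng.uniform(5, 12, n_days),
            "irrigation_mm": rng.uniform(0, 6, n_days),
        },
        index=idx,
    )
    return df
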