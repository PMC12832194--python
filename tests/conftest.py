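import numpy as np
import pandas as pd
import pytest

from drought_greenness import ScenarioConfig, generate_scenario, simulate_climate


@pytest.fixture(scope="session")
def default_config() -> ScenarioConfig:
    return ScenarioConfig(seed=1)


@pytest.fixture(scope="session")
def climate_station(default_config):
    """First synthetic station of the default 21-year scenario."""
    stations, _ = simulate_climate(default_config)
    return stations[0]


@pytest.fixture(scope="session")
def scenario(default_config):
    """Full default scenario (60x60 grid, 21 years, one planted drought)."""
    return generate_scenario(default_config, with_hydrothermal=True)


def monthly_series(values, start="2001-01"):
    """Helper: a monthly pandas Series starting at ``start``."""
    idx = pd.period_range(start, periods=len(values), freq="M")
    return pd.Series(np.asarray(values, dtype=float), index=idx)
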