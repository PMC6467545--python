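import numpy as np
import pytest

from stockiaq import simulator as sim
from stockiaq import synthetic_data as synth


@pytest.fixture(scope="session")
def weather():
    """One seeded synthetic weather year shared across tests."""
    return synth.generate_weather(seed=3)


@pytest.fixture(scope="session")
def thermal_drivers(weather):
    thermal = sim.ThermalParams()
    return sim.year_thermal_drivers(weather, thermal)


@pytest.fixture(scope="session")
def constant_weather():
    """Windless, isothermal weather for closed-form comparisons."""
    import pandas as pd
    n = synth.HOURS_PER_YEAR
    return pd.DataFrame({
        "hour": np.arange(n),
        "outdoor_temperature": np.full(n, 15.0),
        "wind_speed": np.full(n, 4.0),
    })
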