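import numpy as np
import pytest
from hypothesis import settings

from edfm import engine as EN
from edfm.physiology import LightUseParams, WaterParams
from edfm.synthdata import EnvironmentDay

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dry_run():
    """120-day water-limited season (seed 7), shared across tests."""
    config, weather = EN.default_water_limited_scenario(seed=7, n_days=120)
    return config, weather, EN.run_season(config, weather)


@pytest.fixture(scope="session")
def wet_run():
    """Paired irrigated season with the same seed as dry_run."""
    config, weather = EN.well_watered_scenario(seed=7, n_days=120)
    return config, weather, EN.run_season(config, weather)


@pytest.fixture(scope="session")
def unlimited_run():
    """Constant optimal environment, no water stress, carbon non-limiting."""
    config = EN.SimulationConfig(
        fusion_mode="off",
        water=WaterParams(psi_root=0.0),
        lue=LightUseParams(lue=1e6),
    )
    theta = np.full(3, config.water.theta_fc)
    weather = [
        EnvironmentDay(d, 25.0, 25.0, 25.0, 45.0, theta.copy()) for d in range(80)
    ]
    return config, weather, EN.run_season(config, weather)
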