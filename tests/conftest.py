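import numpy as np
import pandas as pd
import pytest

from thermonorms import SimulationConfig, TPCModel, simulate_plate_experiment


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Three-strain panel on a reduced grid, for fast I/O round-trips."""
    full = SimulationConfig(seed=2)
    return SimulationConfig(
        strains=full.strains[:3],
        temperatures=(17.0, 37.0, 46.0),
        seed=2,
    )


@pytest.fixture(scope="session")
def small_plate(small_config):
    return simulate_plate_experiment(small_config)


@pytest.fixture
def sharp_model() -> TPCModel:
    return TPCModel("sharp_drop", t_min=8.0, t_opt_lo=37.0, t_opt_hi=37.0, t_max=41.0, mu_max=1.4)


@pytest.fixture
def plateau_model() -> TPCModel:
    return TPCModel("plateau", t_min=6.0, t_opt_lo=32.0, t_opt_hi=40.0, t_max=48.0, mu_max=0.9)


def make_meta(strains, lineage="Bc", environment="T") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain_id": list(strains),
            "lineage": [lineage] * len(strains),
            "environment": [environment] * len(strains),
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
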