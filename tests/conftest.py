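import numpy as np
import pytest

from tigrisim import DemographyParams, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """Desk-scale config: 100 founders, short horizon, Fast deterministic."""
    return SimulationConfig(
        regime="deterministic", period=3, initial_n=100, horizon=20,
        master_seed=7,
    )


@pytest.fixture
def default_params():
    return DemographyParams()
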