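import numpy as np
import pytest

from vtescan.simulate import SimulationConfig, generate_family_exomes


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def family(default_config):
    return generate_family_exomes(default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
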