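import numpy as np
import pytest

from hccsim import (
    ModelParams,
    SimulationConfig,
    UnprintedParams,
    calibrated_defaults,
)


@pytest.fixture(scope="session")
def base_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def calib_unprinted() -> UnprintedParams:
    return calibrated_defaults()


@pytest.fixture()
def small_config() -> SimulationConfig:
    return SimulationConfig(n_patients=2_000, seed=42)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
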