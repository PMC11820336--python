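import numpy as np
import pytest

from speclive import build_sensor_model, make_operator
from speclive.grids import DEFAULT_GRID


@pytest.fixture(scope="session")
def sensor():
    """Default synthetic 16-channel sensor (deterministic)."""
    return build_sensor_model(seed=0)


@pytest.fixture(scope="session")
def operator(sensor):
    """Default Tikhonov operator for the session sensor."""
    return make_operator(sensor.response, grid=sensor.grid)


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
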