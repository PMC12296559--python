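import numpy as np
import pytest

from bindwave.headmodel import build_grid, fibonacci_sensors, octant_labels, spherical_leadfield


@pytest.fixture(scope="session")
def sensors():
    return fibonacci_sensors(24, radius=0.09)


@pytest.fixture(scope="session")
def grid():
    return octant_labels(build_grid(0.06, 0.015))


@pytest.fixture(scope="session")
def leadfield(grid, sensors):
    return spherical_leadfield(grid, sensors)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
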