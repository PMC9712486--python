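import numpy as np
import pytest

from acsforage.engine import SimulationConfig
from acsforage.landscape import Landscape, LandscapeSpec, init_resources
from acsforage.movement import MovementParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Four-cluster landscape scaled for fast unit tests."""
    return LandscapeSpec(L=400.0, k=4, g=32.0, u=0.05)


@pytest.fixture
def small_landscape(small_spec, rng):
    return Landscape.generate(small_spec, rng)


@pytest.fixture
def small_pool(small_landscape, rng):
    return init_resources(small_landscape, rng)


@pytest.fixture
def quick_sim():
    """Short run configuration for engine-level tests."""
    return SimulationConfig(
        n_individuals=10, total_steps=400, analysis_window=200, seed=7
    )


@pytest.fixture
def default_movement():
    return MovementParams()
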