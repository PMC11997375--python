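import numpy as np
import pytest

from continuum import Bounds, Kernel, RegulationModel, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_bounds():
    return Bounds(0.0, 10.0, 0.0, 10.0)


@pytest.fixture
def gaussian_kernel():
    return Kernel("gaussian", 1.0)


def small_homogeneous_config(**overrides):
    """A quick-to-run homogeneous configuration used by several suites."""
    defaults = dict(
        bounds=Bounds(0, 15, 0, 15, "reprising"),
        K=4.0,
        regulation=RegulationModel.beverton_holt_mortality(1.0),
        interaction=Kernel("gaussian", 1.0),
        dispersal=Kernel("gaussian", 1.0),
        mating=Kernel("gaussian", 1.0),
        seed=0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture
def homogeneous_config():
    return small_homogeneous_config()
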