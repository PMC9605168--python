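import numpy as np
import pytest

from protolattice import InitialConditionSpec, LatticeConfig, RunConfig, initialize_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_lattice():
    return LatticeConfig(10, 10)


@pytest.fixture
def standard_small_grid(rng):
    """Standard initial condition on a small grid (fast to step)."""
    cfg = LatticeConfig(20, 20)
    return initialize_grid(cfg, InitialConditionSpec(), rng), cfg


def make_run_config(size=40, steps=100, seed=1, **kw) -> RunConfig:
    return RunConfig(lattice=LatticeConfig(size, size), steps=steps, seed=seed, **kw)
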