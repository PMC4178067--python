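import numpy as np
import pytest

from mvgmdr import EpistasisModel, RunConfig, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return RunConfig(seed=0)


@pytest.fixture(scope="session")
def strong_digenic():
    """A small dataset with an overwhelming planted digenic interaction."""
    sim = SimulationConfig(n=600, L=6, model=EpistasisModel.antidiagonal(),
                           h2=(0.5, 0.5))
    return simulate_dataset(sim, 202)


@pytest.fixture(scope="session")
def null_dataset():
    """A benchmark-sized dataset with no genetic effect at all."""
    sim = SimulationConfig(n=1000, L=10, h2=(0.0, 0.0))
    return simulate_dataset(sim, 303)
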