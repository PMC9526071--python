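import numpy as np
import pytest

from wolbscan import SimulationConfig, simulate_truth


@pytest.fixture
def small_config():
    """A small but non-trivial survey: 6 localities, 3 strains."""
    return SimulationConfig(
        n_localities=6, individuals_per_locality=12, seed=42)


@pytest.fixture
def small_truth(small_config):
    return simulate_truth(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
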