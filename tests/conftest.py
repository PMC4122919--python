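import numpy as np
import pytest

from mitopopcons import SyntheticConfig, generate_layout, simulate_site_alleles
from mitopopcons.popcons_hmm import HmmParams


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic dataset shared across tests (read-only)."""
    config = SyntheticConfig(seed=11)
    annotations, truth = generate_layout(config)
    sites = simulate_site_alleles(config, truth, seed=12)
    return config, annotations, truth, sites


@pytest.fixture
def rng():
    return np.random.default_rng(20140609)


def random_hmm_params(rng) -> HmmParams:
    transition = rng.dirichlet(np.ones(2), size=2)
    emission = rng.dirichlet(np.ones(4), size=2)
    initial = rng.dirichlet(np.ones(2))
    return HmmParams(transition, emission, initial)
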