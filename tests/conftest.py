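import numpy as np
import pytest

from ssblup.pipeline import true_variance_components
from ssblup.simdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """A small population reused across unit tests."""
    return SimConfig(n_founders=40, n_generations=3, females_per_generation=60,
                     males_per_generation=8, n_chromosomes=3,
                     snps_per_chromosome=60, n_qtl=8, prop_genotyped=0.4,
                     h2=0.37, repeatability=0.5, var_hys=0.1, seed=1)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_vc(tiny_config):
    return true_variance_components(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
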