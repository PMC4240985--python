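import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hybparent import simgen

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_cfg():
    """A compact simulation used across tests: 6 species, 6 loci,
    8 F1 cultivars from a 4-species pool, zero noise."""
    return simgen.SimConfig(
        n_species=6,
        n_nuclear_loci=6,
        locus_length_range=(300, 800),
        n_cultivars=8,
        parental_pool_size=4,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simgen.simulate_dataset(small_cfg)
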