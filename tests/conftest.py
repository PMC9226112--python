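import numpy as np
import pytest

from drivenet.cohort import CohortConfig, generate_cohort, generate_network


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A scaled-down cohort for fast unit tests (same structure as defaults)."""
    return CohortConfig(
        n_genes=400,
        n_tumor=60,
        n_normal=30,
        n_meth_driven=10,
        n_cna_driven=10,
        n_mut_driven=10,
        n_drg=12,
        n_de_extra=40,
        n_cna_passenger=10,
        module_filler=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_network(small_config, small_cohort):
    _, truth = small_cohort
    return generate_network(small_config, truth)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
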