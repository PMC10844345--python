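import numpy as np
import pytest

from surfstab.synthetic import (default_atlas, default_config, default_mesh,
                                simulate_cohort)


@pytest.fixture(scope="session")
def mesh162():
    return default_mesh()


@pytest.fixture(scope="session")
def atlas12(mesh162):
    return default_atlas(mesh162)


@pytest.fixture(scope="session")
def full_mask(mesh162):
    return np.ones(mesh162.n_vertices, dtype=bool)


@pytest.fixture(scope="session")
def regime_config():
    return default_config()


@pytest.fixture(scope="session")
def cohort15():
    """Default-condition cohort (15 vs 15), shared across group-level tests."""
    return simulate_cohort(n_per_group=15, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
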