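import numpy as np
import pytest

from scmethclust.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """40 cells x 300 CpGs in 10 regions, 3 clusters, 50% missing."""
    return simulate_dataset(
        n_cells=40, n_loci=300, n_regions=10, n_clusters=3,
        missing_prop=0.5, seed=1,
    )


@pytest.fixture(scope="session")
def sparse_dataset():
    """High-missingness dataset that makes assignments uncertain."""
    return simulate_dataset(
        n_cells=60, n_loci=400, n_regions=10, n_clusters=3,
        missing_prop=0.9, seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
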