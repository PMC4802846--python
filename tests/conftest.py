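import numpy as np
import pytest

from geqtl import SimConfig, simulate_dataset, standardize


@pytest.fixture(scope="session")
def small_dataset():
    """A 30-SNP x 30-gene x 40-sample dataset with one block + diagonal."""
    config = SimConfig(
        K=30, N=30, H=40,
        blocks=((2, 12, 6, 6),),
        phi=0.1, tau=0.1, J=3, seed=11,
    )
    X, Z, truth = simulate_dataset(config)
    return X, Z, truth


@pytest.fixture(scope="session")
def small_std(small_dataset):
    """Standardized (X, Z) arrays of the small dataset."""
    X, Z, truth = small_dataset
    return standardize(X.values), standardize(Z.values), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
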