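import numpy as np
import pytest

from ipco import FeatureTable, TableRole, simulate_paired


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def counts_table(rng) -> FeatureTable:
    vals = rng.integers(0, 50, size=(8, 5)).astype(float)
    vals[0, 0] += 1  # guard against an all-zero first column
    return FeatureTable(vals, [f"otu{i}" for i in range(8)],
                        [f"s{j}" for j in range(5)], TableRole.TAXONOMIC)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """The standard benchmark community: defaults, no functional noise."""
    return simulate_paired(seed=42, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick community for pipeline-level tests."""
    return simulate_paired(n_taxa=40, n_functions=15, n_samples=24,
                           depth=5000, noise_sd=0.0, seed=11)
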