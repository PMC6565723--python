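import numpy as np
import pytest

from telesim import SimulationConfig, io, simulate_true_counts
from telesim._rng import substream


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def example_tree():
    return io.load_example_tree()


@pytest.fixture(scope="session")
def gene_length_table():
    return io.load_gene_lengths()["length_bp"].to_numpy()


@pytest.fixture(scope="session")
def reference_params():
    return io.load_reference_params()


@pytest.fixture(scope="session")
def small_true_result():
    """One shared small simulation: 5 populations, 120 genes, 100 cells."""
    config = SimulationConfig(n_genes=120, n_cells=100, sigma=0.5, seed=7)
    return simulate_true_counts(config, rng=substream(7, "true_counts"))
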