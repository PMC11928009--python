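import numpy as np
import pytest

from moglearn import SimulationConfig, simulate_multiomics, simulate_null


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_samples_per_class=15,
        n_classes=3,
        n_features={"mrna": 60, "mirna": 20, "methylation": 60},
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_multiomics(small_config)


@pytest.fixture(scope="session")
def null_dataset(small_config):
    return simulate_null(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_graph(rng, n_nodes, p_edge=0.2):
    """Random undirected graph as (adjacency, directed edge_index)."""
    A = (rng.random((n_nodes, n_nodes)) < p_edge).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    src, dst = np.nonzero(A)
    return A, np.vstack([src, dst])
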