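import numpy as np
import pytest
import scipy.sparse as sp

from sgcd.graph_io import GeneNetwork, LabelSet
from sgcd.model import ModelConfig


def make_network(edges, n, f=4, seed=0, features=None):
    """Small dense-free network with random [0,1] features."""
    gene_ids = [f"G{i}" for i in range(n)]
    if edges:
        rows = [e[0] for e in edges] + [e[1] for e in edges]
        cols = [e[1] for e in edges] + [e[0] for e in edges]
        adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        adj.data[:] = 1.0
    else:
        adj = sp.csr_matrix((n, n))
    if features is None:
        features = np.random.default_rng(seed).random((n, f))
    net = GeneNetwork(gene_ids=gene_ids, adjacency=adj, features=features)
    return net


def random_network(rng, n, p=0.3, f=4):
    mask = rng.random((n, n)) < p
    upper = np.triu(mask, k=1)
    edges = list(zip(*np.nonzero(upper)))
    return make_network(edges, n, f=f, seed=int(rng.integers(1 << 30)))


@pytest.fixture
def toy_net():
    """Path graph 0-1-2-3 with 4 features."""
    return make_network([(0, 1), (1, 2), (2, 3)], n=4)


@pytest.fixture
def toy_labels():
    return LabelSet(positives={"G0", "G2"}, negatives={"G1", "G3"})


@pytest.fixture
def small_config():
    return ModelConfig(hidden_dim=4, head_dim=4, num_layers=2, epochs=5, seed=0)


# ---------------------------------------------------------------------------
# Heavy shared experiments (session scope, reused by acceptance checks)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def hetero_study():
    """Variant AUPRCs over 10 fresh heterophilic fixtures (seeds 0..9)."""
    from sgcd.benchmarks import variant_auprcs

    return variant_auprcs(range(10))


@pytest.fixture(scope="session")
def explainer_study():
    """Planted-edge recovery benchmark result."""
    from sgcd.benchmarks import explainer_benchmark

    return explainer_benchmark(seed=3, n_explained=10)
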