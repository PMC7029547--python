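import numpy as np
import pytest

from grlnmf.dataio import SyntheticScenario, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_similarity(rng, p):
    """Random valid similarity matrix: symmetric, [0,1], unit diagonal."""
    S = rng.uniform(size=(p, p))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    return S


@pytest.fixture
def small_planted():
    """Noiseless planted instance small enough for exhaustive checks."""
    scenario = SyntheticScenario(n=20, m=15, rank=3, density=0.1, noise_sd=0.0, seed=7)
    return generate_synthetic(scenario)


def random_dag_edges(rng, n_nodes, extra_edge_prob=0.3):
    """Random DAG as child->parent edges over a topological node order.

    Node i may attach to any earlier node; extra edges create diamonds.
    """
    names = [f"d{i}" for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):
        parent = int(rng.integers(0, i))
        edges.append((names[i], names[parent]))
        for j in range(i):
            if j != parent and rng.uniform() < extra_edge_prob / i:
                edges.append((names[i], names[j]))
    return names, edges
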