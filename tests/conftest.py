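import numpy as np
import pytest

from restconn import BinaryGraph, ConnectivityMatrix, load_atlas, load_networks


def make_graph(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryGraph(a, tuple(f"n{i}" for i in range(n)))


def make_matrix(values):
    v = np.asarray(values, dtype=float)
    return ConnectivityMatrix(v, tuple(f"n{i}" for i in range(v.shape[0])), "r")


def random_r_matrix(rng, n):
    """Random symmetric nonnegative correlation-like matrix, zero diagonal."""
    v = rng.uniform(0.0, 1.0, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return make_matrix(v)


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture(scope="session")
def networks():
    return load_networks()


@pytest.fixture
def k12_minus_edge():
    """Complete 12-node graph with one edge removed: the control
    visual-network topology implied by 130 directed connections."""
    a = np.ones((12, 12), dtype=int) - np.eye(12, dtype=int)
    a[0, 1] = a[1, 0] = 0
    return BinaryGraph(a, tuple(f"n{i}" for i in range(12)))
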