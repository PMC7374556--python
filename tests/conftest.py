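import numpy as np
import pytest

from petnet.network import ThresholdedGraph


def graph_from_adjacency(a, weights=None) -> ThresholdedGraph:
    """ThresholdedGraph wrapper for hand-built adjacency matrices."""
    a = np.asarray(a, dtype=np.int8)
    n = a.shape[0]
    w = np.asarray(weights, dtype=float) if weights is not None else a.astype(float)
    density = a.sum() / (n * (n - 1)) if n > 1 else 1.0
    return ThresholdedGraph(a, w, [f"roi_{i:03d}" for i in range(n)], density)


@pytest.fixture
def make_graph():
    return graph_from_adjacency


def complete_adjacency(n):
    a = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(a, 0)
    return a


def star_adjacency(n_leaves):
    a = np.zeros((n_leaves + 1, n_leaves + 1), dtype=np.int8)
    a[0, 1:] = 1
    a[1:, 0] = 1
    return a


def path_adjacency(n):
    a = np.zeros((n, n), dtype=np.int8)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return a


def two_triangles_adjacency():
    a = np.zeros((6, 6), dtype=np.int8)
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                if i != j:
                    a[i, j] = 1
    return a
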