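import numpy as np
import pytest

from dircp.graph import DCPParams, DirectedGraph, Partition, sample_dcp


def graph_from_edges(n, edges, labels=None):
    """Small-graph helper: build a DirectedGraph from (u, v) index pairs."""
    adj = np.zeros((n, n), dtype=np.int8)
    for u, v in edges:
        adj[u, v] = 1
    return DirectedGraph(adj, labels or tuple(f"v{i}" for i in range(n)))


def random_graph(n, density, seed):
    rng = np.random.default_rng(seed)
    adj = (rng.random((n, n)) < density).astype(np.int8)
    return DirectedGraph(adj, tuple(f"v{i}" for i in range(n)))


@pytest.fixture(scope="session")
def perfect_small():
    """DCP(1, 0) with sizes (2, 2, 2, 2): the exact idealized L, 20 edges."""
    return sample_dcp(DCPParams((2, 2, 2, 2), 1.0, 0.0), seed=0)


@pytest.fixture(scope="session")
def perfect_100():
    """DCP(1, 0) with four sets of 25 nodes."""
    return sample_dcp(DCPParams((25, 25, 25, 25), 1.0, 0.0), seed=0)


@pytest.fixture(scope="session")
def noisy_mid():
    """DCP(0.9, 0.1) with four sets of 25 nodes: strong but noisy signal."""
    return sample_dcp(DCPParams((25, 25, 25, 25), 0.9, 0.1), seed=11)
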