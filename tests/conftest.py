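import networkx as nx
import numpy as np
import pytest

from relaycomm.connectome import StructuralConnectome, euclidean_weighting
from relaycomm.io import RegionTable


def make_regions(centroids, systems=None, modality=None, hemisphere=None, names=None):
    n = len(centroids)
    if names is None:
        names = [f"R{i:03d}" for i in range(n)]
    if systems is None:
        systems = ["VIS"] * n
    if modality is None:
        modality = ["unimodal"] * n
    return RegionTable(
        names=names,
        centroids=np.asarray(centroids, dtype=float),
        systems=systems,
        modality_class=modality,
        hemisphere=hemisphere,
    )


def make_connectome(adjacency, centroids):
    regions = make_regions(centroids)
    return euclidean_weighting(np.asarray(adjacency), regions)


def random_connectome(rng, n=10, p=0.4):
    """Random connected weighted graph with generic (tie-free) distances."""
    while True:
        adjacency = (rng.random((n, n)) < p).astype(int)
        adjacency = np.triu(adjacency, 1)
        adjacency = adjacency + adjacency.T
        centroids = rng.uniform(0, 100, size=(n, 3))
        g = nx.from_numpy_array(adjacency)
        if nx.is_connected(g):
            return make_connectome(adjacency, centroids)


def brute_force_k_shortest(conn, i, j, k):
    """Exhaustive simple-path enumeration sorted by (length, name sequence)."""
    g = conn.graph()
    names = conn.regions.names
    scored = []
    for p in nx.all_simple_paths(g, i, j):
        length = sum(conn.weights[a, b] for a, b in zip(p[:-1], p[1:]))
        scored.append((length, tuple(names[v] for v in p), tuple(p)))
    scored.sort()
    return [(path, length) for length, _, path in scored[:k]]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle():
    """3-4-5 right triangle, fully connected."""
    adjacency = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
    centroids = [(0, 0, 0), (3, 4, 0), (6, 0, 0)]
    return make_connectome(adjacency, centroids)


@pytest.fixture
def line_graph():
    """a - b - c line."""
    adjacency = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    centroids = [(0, 0, 0), (3, 4, 0), (6, 0, 0)]
    return make_connectome(adjacency, centroids)
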