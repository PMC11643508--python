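import numpy as np
import pytest
from hypothesis import settings

from simpliciality import Hypergraph, SizeRestriction, build_hypergraph

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def random_hypergraph(rng, max_nodes=12, max_edges=40, max_edge_size=6):
    """A random simple hypergraph on a small node set, for oracle tests."""
    n = int(rng.integers(3, max_nodes + 1))
    m = int(rng.integers(1, max_edges + 1))
    edges = []
    for _ in range(m):
        s = int(rng.integers(2, min(max_edge_size, n) + 1))
        edges.append(rng.choice(n, size=s, replace=False).tolist())
    return build_hypergraph(edges)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def restriction():
    return SizeRestriction()


@pytest.fixture
def open_triangle():
    """A triangle with one pair present: SF 0, ES 1/3, FES 1/3."""
    return build_hypergraph([[1, 2, 3], [1, 2]])


@pytest.fixture
def closed_triangle():
    """A triangle with all pairs: a (restricted) simplicial complex."""
    return build_hypergraph([[1, 2, 3], [1, 2], [1, 3], [2, 3]])


@pytest.fixture
def two_triangles():
    """One closed and one empty triangle: SF = ES = FES = 1/2."""
    return build_hypergraph([[1, 2, 3], [4, 5, 6], [1, 2], [1, 3], [2, 3]])
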