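import numpy as np
import pytest

from scpotency import EdgeList, ExpressionMatrix, max_connected_component


def make_net(*edges):
    """PPINetwork from explicit edges, e.g. make_net(('a','b'), ('b','c'))."""
    return max_connected_component(EdgeList(edges=list(edges)))


@pytest.fixture
def path_net():
    """Path a-b-c: degrees (1, 2, 1)."""
    return make_net(("a", "b"), ("b", "c"))


@pytest.fixture
def star_net():
    """Star with center c and leaves l1..l3: degrees (3, 1, 1, 1)."""
    return make_net(("c", "l1"), ("c", "l2"), ("c", "l3"))


def complete_net(n):
    names = [f"n{i}" for i in range(n)]
    return make_net(*[(names[i], names[j]) for i in range(n) for j in range(i + 1, n)])


@pytest.fixture
def counts_matrix():
    """5 genes x 4 cells toy counts with zeros and a duplicate-free gene set."""
    vals = np.array(
        [
            [0, 5, 0, 2],
            [1, 0, 3, 0],
            [4, 4, 4, 4],
            [0, 0, 0, 9],
            [2, 1, 0, 1],
        ],
        dtype=float,
    )
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3", "g4", "g5"],
        cell_ids=["c1", "c2", "c3", "c4"],
        values=vals,
        layer="counts",
    )


def random_connected_net(rng, n_min=5, n_max=20):
    """A small random connected graph: random tree plus random extra edges."""
    n = int(rng.integers(n_min, n_max + 1))
    names = [f"v{i:02d}" for i in range(n)]
    edges = set()
    for i in range(1, n):  # random tree guarantees connectivity
        j = int(rng.integers(0, i))
        edges.add(tuple(sorted((names[i], names[j]))))
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        i, j = rng.choice(n, size=2, replace=False)
        edges.add(tuple(sorted((names[int(i)], names[int(j)]))))
    return make_net(*edges)
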