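import numpy as np
import pytest
import scipy.sparse as sp

from sigsel import CellGraph


def random_graph(seed: int, n: int, density: float = 0.6,
                 connected: bool = True) -> CellGraph:
    """Random connected weighted graph (test helper)."""
    rng = np.random.default_rng(seed)
    for _ in range(200):
        A = np.where(rng.random((n, n)) < density,
                     rng.uniform(0.5, 1.5, (n, n)), 0.0)
        A = np.triu(A, 1)
        A = A + A.T
        if not A.sum(axis=1).all():
            continue
        G = CellGraph.from_adjacency(sp.csr_matrix(A))
        if not connected or G.is_connected():
            return G
    raise RuntimeError("could not sample a connected graph")


@pytest.fixture
def path_graph():
    """Unit-weight path a-c-b with node order (a, b, c): degrees (1, 1, 2)."""
    A = np.array([[0.0, 0.0, 1.0],
                  [0.0, 0.0, 1.0],
                  [1.0, 1.0, 0.0]])
    return CellGraph.from_adjacency(sp.csr_matrix(A),
                                    node_ids=np.array(list("abc"), dtype=object))


@pytest.fixture
def triangle():
    """Unit-weight triangle: degrees (2, 2, 2)."""
    A = np.ones((3, 3)) - np.eye(3)
    return CellGraph.from_adjacency(sp.csr_matrix(A))


@pytest.fixture
def complete_graph():
    A = np.ones((12, 12)) - np.eye(12)
    return CellGraph.from_adjacency(sp.csr_matrix(A))
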