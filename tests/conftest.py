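import numpy as np
import pytest

from pcnkit.network import ContactNetwork


def net_from(A) -> ContactNetwork:
    A = np.asarray(A, dtype=int)
    return ContactNetwork(A=A, labels=[f"n{i}" for i in range(A.shape[0])])


def random_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Symmetric binary zero-diagonal G(n, p) adjacency matrix."""
    U = rng.random((n, n))
    upper = np.triu(U < p, k=1)
    return (upper | upper.T).astype(int)


@pytest.fixture
def helix30_net():
    from pcnkit.network import BuildParams, build_adjacency
    from pcnkit.structure_io import extract_nodes, generate_helix_fixture, parse_structure

    model = parse_structure(generate_helix_fixture(30))
    nodes = extract_nodes(model, "ca")
    return build_adjacency(nodes, BuildParams(d_min=4.0, d_max=8.0))


@pytest.fixture
def two_triangles_net():
    """Two disjoint triangles {0,1,2} and {3,4,5}."""
    A = np.zeros((6, 6), dtype=int)
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        A[a, b] = A[b, a] = 1
    return net_from(A)


@pytest.fixture
def barbell_net(two_triangles_net):
    """Two triangles joined by the single bridge edge 2-3 (m = 7)."""
    A = two_triangles_net.A.copy()
    A[2, 3] = A[3, 2] = 1
    return net_from(A)


@pytest.fixture
def k3_net():
    return net_from(1 - np.eye(3, dtype=int))
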