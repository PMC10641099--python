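"""Graph partitioning: spectral clustering, embedded clustering, community
extraction, modularity scoring and a planted-partition fixture generator.

Spectral clustering operates on the graph Laplacian L = D - A (or its
symmetric/random-walk normalized forms); the eigenvectors of its smallest
eigenvalues provide cluster coordinates that are grouped by k-means.
Embedded clustering instead runs k-means on an explicit low-dimensional
node embedding — either the Laplacian eigenmap or a HOPE-style truncated
SVD of the Katz similarity matrix S = (I - βA)^{-1} βA.  Community
extraction offers Louvain, Clauset–Newman–Moore greedy modularity,
asynchronous label propagation, and Girvan–Newman edge-betweenness
removal, all seeded for reproducibility.

All partition labels are renumbered canonically by first node occurrence
so that repeat runs and cross-method comparisons are stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import laplacian as csgraph_laplacian
from sklearn.cluster import KMeans

from .errors import ParameterError
from .network import ContactNetwork, validate_adjacency

LAPLACIAN_VARIANTS = ("unnormalized", "sym", "rw")
EMBED_METHODS = ("laplacian_eigenmap", "hope_katz")
COMMUNITY_METHODS = ("louvain", "greedy_modularity", "label_propagation", "girvan_newman")


@dataclass
class Partition:
    """Node-to-cluster assignment with provenance.

    labels are integers 0..k-1, every label used, renumbered by first
    occurrence over the node order.
    """

    labels: np.ndarray
    k: int
    method: str
    params: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        used = np.unique(self.labels)
        if not np.array_equal(used, np.arange(self.k)):
            raise ParameterError(
                f"partition labels must be 0..{self.k - 1} with every label used"
            )


@dataclass
class Embedding:
    vectors: np.ndarray  # shape (N, d)
    d: int
    method: str
    params: dict = field(default_factory=dict)


def canonical_labels(raw_labels: Sequence[int]) -> np.ndarray:
    """Renumber labels by first occurrence: first node's cluster becomes 0."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw_labels), dtype=int)
    for i, lab in enumerate(raw_labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _laplacian_matrix(net: ContactNetwork, variant: str) -> np.ndarray:
    A = net.A.astype(float)
    if variant == "unnormalized":
        return csgraph_laplacian(A, normed=False)
    if variant in ("sym", "rw"):
        # scipy's normed Laplacian applies the 0-degree convention for
        # isolated nodes (their diagonal stays 0 -> eigenvalue 0).
        return csgraph_laplacian(A, normed=True)
    raise ParameterError(f"unknown Laplacian variant: {variant!r}")


def laplacian_spectrum(net: ContactNetwork, variant: str = "unnormalized") -> np.ndarray:
    """Ascending eigenvalues of the chosen Laplacian.

    L_rw = D^{-1}L is similar to L_sym = D^{-1/2} L D^{-1/2}, so the 'rw'
    spectrum equals the 'sym' spectrum; both use the 0-diagonal
    convention for isolated nodes.  The multiplicity of eigenvalue 0
    equals the number of connected components.
    """
    if net.n_nodes < 2:
        raise ParameterError("spectrum requires at least 2 nodes")
    L = _laplacian_matrix(net, variant)
    vals = np.linalg.eigvalsh(L)
    return np.sort(vals)


def _spectral_coordinates(net: ContactNetwork, k: int, variant: str) -> np.ndarray:
    L = _laplacian_matrix(net, variant)
    vals, vecs = eigh(L)
    order = np.argsort(vals)
    X = vecs[:, order[:k]]
    if variant == "rw":
        # Recover random-walk eigenvectors from the symmetric ones:
        # v_rw = D^{-1/2} v_sym (isolated nodes kept as-is).
        d = net.degrees().astype(float)
        scale = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 1.0)
        X = X * scale[:, None]
    if variant == "sym":
        norms = np.linalg.norm(X, axis=1)
        norms[norms == 0] = 1.0
        X = X / norms[:, None]
    return X


def _kmeans_partition(
    X: np.ndarray, k: int, seed: int, method: str, params: dict
) -> Partition:
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    labels = canonical_labels(raw)
    return Partition(
        labels=labels,
        k=int(labels.max()) + 1,
        method=method,
        params=dict(params, inertia=float(km.inertia_)),
        seed=seed,
    )


def spectral_clustering(
    net: ContactNetwork, k: int, variant: str = "unnormalized", seed: int = 0
) -> Partition:
    """Cluster nodes by k-means on the k smallest Laplacian eigenvectors.

    For the 'sym' variant rows of the eigenvector matrix are normalized
    to unit length before k-means (Ng–Jordan–Weiss).  On a graph with k
    connected components the partition equals the components exactly.
    """
    _check_k(k, net.n_nodes)
    if variant not in LAPLACIAN_VARIANTS:
        raise ParameterError(f"unknown Laplacian variant: {variant!r}")
    X = _spectral_coordinates(net, k, variant)
    return _kmeans_partition(X, k, seed, "spectral", {"variant": variant, "k": k})


def _check_k(k: int, n: int) -> None:
    if not 2 <= k <= n:
        raise ParameterError(f"k must satisfy 2 <= k <= N ({n}); got {k}")


def embed(
    net: ContactNetwork, method: str, d: int, beta: float = 0.05
) -> Embedding:
    """Embed nodes in ℝ^d.

    laplacian_eigenmap: eigenvectors 2..d+1 (ascending eigenvalue) of the
    unnormalized Laplacian — the constant eigenvector is dropped, so
    d <= N-1.  hope_katz: rank-d truncated SVD of the Katz similarity
    S = (I - βA)^{-1} βA with node vectors U_d √Σ_d; requires
    β < 1/ρ(A) for the Katz series to converge.
    """
    N = net.n_nodes
    if method not in EMBED_METHODS:
        raise ParameterError(f"unknown embedding method: {method!r}")
    if d < 1:
        raise ParameterError("embedding dimension d must be >= 1")
    if method == "laplacian_eigenmap":
        if d > N - 1:
            raise ParameterError(
                f"laplacian_eigenmap supports d <= N-1 ({N - 1}); got {d}"
            )
        L = _laplacian_matrix(net, "unnormalized")
        # Deflate the constant eigenvector by shifting it above the spectrum
        # (Gershgorin bound 2·max degree); on disconnected graphs the zero
        # eigenspace is degenerate and plain eigh would otherwise return an
        # arbitrary basis mixing the constant direction in.
        shift = 2.0 * float(L.diagonal().max()) + 1.0
        Ld = L + shift * np.ones((N, N)) / N
        vals, vecs = eigh(Ld)
        X = vecs[:, np.argsort(vals)[:d]]
        for j in range(X.shape[1]):
            col = X[:, j]
            if col[np.argmax(np.abs(col))] < 0:
                X[:, j] = -col
        return Embedding(vectors=X, d=d, method=method)
    # hope_katz
    if d > N:
        raise ParameterError(f"hope_katz supports d <= N ({N}); got {d}")
    A = net.A.astype(float)
    rho = float(np.max(np.abs(np.linalg.eigvalsh(A)))) if net.n_edges else 0.0
    if rho > 0 and beta >= 1.0 / rho:
        raise ParameterError(
            f"Katz series diverges: beta={beta} >= 1/spectral radius ({1.0 / rho:.4g})"
        )
    S = np.linalg.solve(np.eye(N) - beta * A, beta * A)
    U, s, _ = np.linalg.svd(S)
    X = U[:, :d] * np.sqrt(s[:d])
    # fix SVD sign ambiguity: make the largest-magnitude entry of each
    # column nonnegative
    for j in range(X.shape[1]):
        col = X[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            X[:, j] = -col
    return Embedding(vectors=X, d=d, method=method, params={"beta": beta})


def embedded_clustering(
    net: ContactNetwork,
    method: str,
    d: int,
    k: int,
    seed: int = 0,
    beta: float = 0.05,
) -> Partition:
    """k-means on a node embedding (same k-means contract as spectral)."""
    _check_k(k, net.n_nodes)
    emb = embed(net, method, d, beta=beta)
    return _kmeans_partition(
        emb.vectors, k, seed, f"embedded:{method}", {"d": d, "k": k, **emb.params}
    )


def community_detect(
    net: ContactNetwork,
    method: str,
    seed: int = 0,
    k: Optional[int] = None,
    resolution: float = 1.0,
) -> Partition:
    """Extract communities.

    louvain: seeded Louvain at the given resolution.
    greedy_modularity: Clauset–Newman–Moore agglomeration.
    label_propagation: asynchronous, seeded node order, to convergence.
    girvan_newman: repeatedly remove the edge of maximum edge betweenness
        (ties broken by lowest edge index) until at least k components
        remain (k defaults to 2); the partition is the components.
    """
    if method not in COMMUNITY_METHODS:
        raise ParameterError(f"unknown community method: {method!r}")
    if net.n_edges == 0:
        raise ParameterError("community extraction requires at least one edge")
    G = nx.from_numpy_array(net.A)
    params: dict = {}
    if method == "louvain":
        comms = nx.community.louvain_communities(G, resolution=resolution, seed=seed)
        params["resolution"] = resolution
    elif method == "greedy_modularity":
        comms = nx.community.greedy_modularity_communities(G)
    elif method == "label_propagation":
        comms = list(nx.community.asyn_lpa_communities(G, seed=seed))
    else:  # girvan_newman
        target = 2 if k is None else k
        comms = _girvan_newman_components(G, target)
        params["k"] = target

    raw = np.empty(net.n_nodes, dtype=int)
    for cid, members in enumerate(comms):
        for node in members:
            raw[node] = cid
    labels = canonical_labels(raw)
    return Partition(
        labels=labels,
        k=int(labels.max()) + 1,
        method=method,
        params=params,
        seed=seed,
    )


def _girvan_newman_components(G: nx.Graph, k: int) -> list[set[int]]:
    """Remove max-edge-betweenness edges until >= k components remain."""
    H = G.copy()
    while nx.number_connected_components(H) < k:
        if H.number_of_edges() == 0:
            break
        eb = nx.edge_betweenness_centrality(H, normalized=False)
        best = max(eb.values())
        # deterministic tie-break: lowest (i, j) edge among the maxima
        candidates = sorted(
            tuple(sorted(e)) for e, v in eb.items() if v == best
        )
        H.remove_edge(*candidates[0])
    return [set(c) for c in nx.connected_components(H)]


def modularity(net: ContactNetwork, partition: Partition) -> float:
    """Newman modularity Q = Σ_s [e_s/m − (d_s/2m)²].

    e_s is the number of edges inside cluster s, d_s its total degree and
    m the number of edges in the graph.
    """
    if net.n_edges == 0:
        raise ParameterError("modularity requires at least one edge")
    if len(partition.labels) != net.n_nodes:
        raise ParameterError("partition does not match network size")
    m = net.n_edges
    deg = net.degrees()
    Q = 0.0
    for s in range(partition.k):
        members = np.nonzero(partition.labels == s)[0]
        sub = net.A[np.ix_(members, members)]
        e_s = sub.sum() / 2.0
        d_s = deg[members].sum()
        Q += e_s / m - (d_s / (2.0 * m)) ** 2
    return float(Q)


def generate_planted_partition(
    blocks: int, size: int, p_in: float, p_out: float, seed: int = 0
) -> tuple[ContactNetwork, np.ndarray]:
    """Stochastic block model fixture with known ground-truth labels.

    Edges within a block appear with probability p_in, between blocks with
    p_out (p_in > p_out); the returned labels allow ARI scoring of any
    clustering method.
    """
    if not (0.0 <= p_out <= 1.0 and 0.0 <= p_in <= 1.0):
        raise ParameterError("probabilities must lie in [0, 1]")
    if p_in <= p_out:
        raise ParameterError("planted partition requires p_in > p_out")
    if blocks < 1 or size < 1:
        raise ParameterError("blocks and size must be >= 1")
    rng = np.random.default_rng(seed)
    N = blocks * size
    truth = np.repeat(np.arange(blocks), size)
    same = truth[:, None] == truth[None, :]
    P = np.where(same, p_in, p_out)
    U = rng.random((N, N))
    upper = np.triu(U < P, k=1)
    A = (upper | upper.T).astype(int)
    net = ContactNetwork(
        A=A,
        labels=[f"n{i}" for i in range(N)],
        params="external",
    )
    validate_adjacency(net.A)
    return net, truth
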