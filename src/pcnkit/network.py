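"""Contact-network construction and the adjacency-matrix text dialect.

A protein contact network is the undirected graph whose nodes are residues
and whose edges are residue pairs with representative-point Euclidean
distance inside an inclusive window [d_min, d_max].  The lower cutoff
(classically 4 Å) excludes trivially close covalent neighbours along the
backbone; the upper cutoff (classically 8 Å) bounds what counts as a
significant non-covalent contact.

Networks can also be loaded from a plain-text adjacency file:

    # labels: A:1 A:2 A:3        (optional header)
    0 1 0
    1 0 1
    0 1 0

Matrices must be square, symmetric, binary and zero-diagonal; anything
else — including weighted matrices — is rejected rather than coerced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import MatrixFormatError, ParameterError
from .structure_io import REPRESENTATIONS, ResidueNode

EXTERNAL = "external"


@dataclass(frozen=True)
class BuildParams:
    """Parameters of a contact-network build.

    d_min/d_max are the inclusive distance window in Å; min_seq_sep
    suppresses contacts between residues closer than that many sequence
    positions on the same chain (0 = no suppression, the default).
    """

    mode: str = "ca"
    d_min: float = 4.0
    d_max: float = 8.0
    min_seq_sep: int = 0
    chains: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.mode not in REPRESENTATIONS:
            raise ParameterError(f"unknown representation mode: {self.mode!r}")
        if self.d_min < 0:
            raise ParameterError("d_min must be >= 0")
        if self.d_min >= self.d_max:
            raise ParameterError(
                f"d_min ({self.d_min}) must be strictly less than d_max ({self.d_max})"
            )
        if self.min_seq_sep < 0:
            raise ParameterError("min_seq_sep must be >= 0")


@dataclass
class ContactNetwork:
    """A binary, symmetric, zero-diagonal adjacency matrix with node labels."""

    A: np.ndarray
    labels: list[str]
    nodes: Optional[list[ResidueNode]] = None
    params: Union[BuildParams, str] = EXTERNAL

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=int)
        validate_adjacency(self.A)
        if len(self.labels) != self.A.shape[0]:
            raise MatrixFormatError(
                f"{len(self.labels)} labels for a {self.A.shape[0]}-node matrix"
            )
        if self.nodes is not None and len(self.nodes) != self.A.shape[0]:
            raise MatrixFormatError("node list length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.A.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.A.sum(axis=1)


def validate_adjacency(A: np.ndarray) -> None:
    """Raise :class:`MatrixFormatError` unless A is a valid PCN adjacency."""
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise MatrixFormatError("matrix not square")
    if not np.isin(A, (0, 1)).all():
        raise MatrixFormatError("matrix not binary")
    if not np.array_equal(A, A.T):
        raise MatrixFormatError("matrix not symmetric")
    if np.any(np.diag(A) != 0):
        raise MatrixFormatError("nonzero diagonal")


def build_adjacency(nodes: Sequence[ResidueNode], params: BuildParams) -> ContactNetwork:
    """Build the binary adjacency matrix over residue nodes.

    A[i,j] = 1 iff d_min <= ||coord_i - coord_j|| <= d_max (inclusive on
    both ends) and the pair is either on different chains or at sequence
    separation |res_seq_i - res_seq_j| >= min_seq_sep.  Nodes are sorted
    by (chain, res_seq, i_code) and re-indexed, so the result does not
    depend on input order.
    """
    if len(nodes) < 2:
        raise ParameterError("need at least 2 nodes to build a network")
    ordered = sorted(nodes, key=lambda n: (n.chain_id, n.res_seq, n.i_code))
    ordered = [
        ResidueNode(
            index=i,
            chain_id=n.chain_id,
            res_seq=n.res_seq,
            i_code=n.i_code,
            res_name=n.res_name,
            coord=n.coord,
            representation=n.representation,
        )
        for i, n in enumerate(ordered)
    ]
    coords = np.array([n.coord for n in ordered], dtype=float)
    D = squareform(pdist(coords))
    within = (D >= params.d_min) & (D <= params.d_max)

    chains = np.array([n.chain_id for n in ordered])
    seqs = np.array([n.res_seq for n in ordered])
    sep_ok = (chains[:, None] != chains[None, :]) | (
        np.abs(seqs[:, None] - seqs[None, :]) >= params.min_seq_sep
    )

    A = (within & sep_ok).astype(int)
    np.fill_diagonal(A, 0)
    return ContactNetwork(
        A=A, labels=[n.label for n in ordered], nodes=ordered, params=params
    )


def write_adjacency_file(net: ContactNetwork) -> str:
    """Serialize a network to the adjacency text dialect (deterministic bytes)."""
    header = "# labels: " + " ".join(net.labels)
    rows = [" ".join(str(v) for v in row) for row in net.A]
    return header + "\n" + "\n".join(rows) + "\n"


def read_adjacency_file(text: str) -> ContactNetwork:
    """Parse the adjacency text dialect back into a :class:`ContactNetwork`.

    The label header is optional; absent labels default to n0..n{N-1}.
    Non-square, non-symmetric, non-binary or nonzero-diagonal matrices are
    rejected with a :class:`MatrixFormatError`.
    """
    labels: Optional[list[str]] = None
    rows: list[list[int]] = []
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.startswith("labels:"):
                labels = body[len("labels:"):].split()
            continue
        row = []
        for tok in stripped.split():
            try:
                v = int(tok)
            except ValueError as exc:
                raise MatrixFormatError(f"matrix not binary: entry {tok!r}") from exc
            if v not in (0, 1):
                raise MatrixFormatError(f"matrix not binary: entry {tok!r}")
            row.append(v)
        rows.append(row)
    if not rows:
        raise MatrixFormatError("empty adjacency file")
    n = len(rows)
    if any(len(r) != n for r in rows):
        raise MatrixFormatError("matrix not square")
    A = np.array(rows, dtype=int)
    if labels is None:
        labels = [f"n{i}" for i in range(n)]
    if len(labels) != n:
        raise MatrixFormatError(f"{len(labels)} labels for a {n}-node matrix")
    return ContactNetwork(A=A, labels=labels, params=EXTERNAL)


def contact_pairs(net: ContactNetwork) -> list[tuple[str, str]]:
    """Upper-triangle edge list as (label_i, label_j) pairs, index-ordered."""
    ii, jj = np.nonzero(np.triu(net.A, k=1))
    return [(net.labels[i], net.labels[j]) for i, j in zip(ii.tolist(), jj.tolist())]


def contact_pairs_tsv(net: ContactNetwork) -> str:
    """Edge list as 2-column TSV with header node_i / node_j."""
    lines = ["node_i\tnode_j"]
    lines += [f"{a}\t{b}" for a, b in contact_pairs(net)]
    return "\n".join(lines) + "\n"
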