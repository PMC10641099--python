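"""Guimerà–Amaral network cartography: participation coefficient P and
intramodular connectivity z-score.

Given a contact network and any partition of it, each node i with total
degree k_i and κ_is edges into cluster s has

    P_i = 1 − Σ_s (κ_is / k_i)²

(0 when all its edges stay in its own cluster, approaching 1 − 1/m for an
even spread over m clusters), and

    z_i = (κ_i − ⟨κ⟩_{s_i}) / σ_{κ, s_i}

where κ_i is the within-module degree and the mean/standard deviation are
taken over the node's own cluster (population σ).  Degenerate cases map
to 0: isolated nodes have P = 0 and clusters with σ = 0 (including
singletons) give z = 0, keeping downstream tables total.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import Partition
from .errors import ParameterError
from .network import ContactNetwork

ZP_COLUMNS = [
    "structure_label",
    "node_index",
    "chain",
    "res_seq",
    "cluster",
    "k",
    "kappa",
    "P",
    "z",
]


def _check_match(net: ContactNetwork, partition: Partition) -> None:
    if len(partition.labels) != net.n_nodes:
        raise ParameterError(
            f"partition covers {len(partition.labels)} nodes but the network "
            f"has {net.n_nodes}"
        )


def _kappa_matrix(net: ContactNetwork, partition: Partition) -> np.ndarray:
    """κ[i, s] = number of edges from node i into cluster s."""
    onehot = np.zeros((net.n_nodes, partition.k), dtype=int)
    onehot[np.arange(net.n_nodes), partition.labels] = 1
    return net.A @ onehot


def participation_coefficient(net: ContactNetwork, partition: Partition) -> np.ndarray:
    """P_i = 1 − Σ_s (κ_is/k_i)²; isolated nodes get P = 0."""
    _check_match(net, partition)
    kappa = _kappa_matrix(net, partition).astype(float)
    k = net.degrees().astype(float)
    safe_k = np.where(k > 0, k, 1.0)
    P = 1.0 - ((kappa / safe_k[:, None]) ** 2).sum(axis=1)
    P[k == 0] = 0.0
    return P


def within_module_degree(net: ContactNetwork, partition: Partition) -> np.ndarray:
    """κ_i: edges from node i into its own cluster."""
    _check_match(net, partition)
    kappa = _kappa_matrix(net, partition)
    return kappa[np.arange(net.n_nodes), partition.labels]


def intramodular_zscore(net: ContactNetwork, partition: Partition) -> np.ndarray:
    """z_i standardizes κ_i against its cluster (population σ; σ=0 → z=0)."""
    _check_match(net, partition)
    kappa = within_module_degree(net, partition).astype(float)
    z = np.zeros(net.n_nodes)
    for s in range(partition.k):
        members = partition.labels == s
        mu = kappa[members].mean()
        sigma = kappa[members].std()  # population (divide-by-n)
        if sigma > 0:
            z[members] = (kappa[members] - mu) / sigma
    return z


def zp_table(
    entries: Sequence[tuple[str, ContactNetwork, Partition]]
) -> pd.DataFrame:
    """Long-format z–P table over one or more structures.

    One row per node per structure, columns :data:`ZP_COLUMNS`.  Structure
    labels must be unique.
    """
    seen: set[str] = set()
    frames = []
    for label, net, partition in entries:
        if label in seen:
            raise ParameterError(f"duplicate structure_label: {label!r}")
        seen.add(label)
        _check_match(net, partition)
        P = participation_coefficient(net, partition)
        z = intramodular_zscore(net, partition)
        kappa = within_module_degree(net, partition)
        if net.nodes is not None:
            chains = [n.chain_id for n in net.nodes]
            seqs: list = [n.res_seq for n in net.nodes]
        else:
            chains = ["" for _ in net.labels]
            seqs = [None for _ in net.labels]
        frames.append(
            pd.DataFrame(
                {
                    "structure_label": label,
                    "node_index": np.arange(net.n_nodes),
                    "chain": chains,
                    "res_seq": seqs,
                    "cluster": partition.labels,
                    "k": net.degrees(),
                    "kappa": kappa,
                    "P": P,
                    "z": z,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[ZP_COLUMNS]
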