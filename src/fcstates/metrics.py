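"""Node-level metrics of binary brain networks.

Degree counts a node's links (functional interaction); the clustering
coefficient is the fraction of realised edges among a node's neighbours
(functional segregation); local efficiency summarises inverse shortest-path
lengths (information transfer).

Local efficiency is exposed in two modes because the printed formula and
the conventional definition differ:

``literal``
    E(i) = (1/N) * sum_{j != i} 1 / L_ij over the *whole* graph, N the
    number of nodes, unreachable pairs contributing 0.  This is a nodal
    efficiency with a 1/N prefactor.
``neighborhood``
    Efficiency of the subgraph induced by the neighbours of i, normalised
    by k_i (k_i - 1); 0 when k_i < 2.  This is the standard local
    efficiency of the complex-network literature.

The mode used is recorded in every output row.
"""

from __future__ import annotations

from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .network import BinaryConnectome

__all__ = [
    "degree",
    "clustering_coefficient",
    "shortest_path_lengths",
    "local_efficiency",
    "node_metric_table",
]

EfficiencyMode = Literal["literal", "neighborhood"]


def degree(net: BinaryConnectome) -> np.ndarray:
    """k_i = number of edges incident to node i (adjacency row sum)."""
    return net.adjacency.sum(axis=1).astype(int)


def clustering_coefficient(net: BinaryConnectome) -> np.ndarray:
    """C_i = E_i / C(k_i, 2), the realised fraction of neighbour pairs.

    E_i counts edges among the neighbours of i.  Nodes with fewer than two
    neighbours have no neighbour pairs; their coefficient is defined as 0.
    """
    a = net.adjacency.astype(float)
    k = a.sum(axis=1)
    # diagonal of A^3 counts 2*E_i closed triples through i
    triangles = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def shortest_path_lengths(net: BinaryConnectome) -> np.ndarray:
    """All-pairs hop-count distances; unreachable pairs are ``inf``."""
    d = _csgraph_shortest_path(net.adjacency, method="D", unweighted=True, directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def _subgraph_efficiency(a_sub: np.ndarray) -> float:
    """Sum over ordered pairs of inverse hop distances in a subgraph."""
    d = _csgraph_shortest_path(a_sub, method="D", unweighted=True, directed=False)
    n = a_sub.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return float(inv.sum())


def local_efficiency(net: BinaryConnectome,
                     mode: EfficiencyMode = "literal") -> np.ndarray:
    if mode not in ("literal", "neighborhood"):
        raise ValueError(f"unknown efficiency mode: {mode!r}")
    a = net.adjacency
    n = net.n_nodes
    if mode == "literal":
        d = shortest_path_lengths(net)
        off = ~np.eye(n, dtype=bool)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
        return inv.sum(axis=1) / n
    eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = nbrs.size
        if k < 2:
            continue
        eff[i] = _subgraph_efficiency(a[np.ix_(nbrs, nbrs)]) / (k * (k - 1))
    return eff


def node_metric_table(nets: Iterable[BinaryConnectome],
                      mode: EfficiencyMode = "literal") -> pd.DataFrame:
    """Tidy per-node metric table across subject-sessions.

    Columns: subject_id, session, group, roi, degree, clustering,
    local_efficiency, mode.
    """
    rows = []
    for net in nets:
        k = degree(net)
        c = clustering_coefficient(net)
        e = local_efficiency(net, mode=mode)
        for idx, roi in enumerate(net.roi_labels):
            rows.append((net.subject_id, net.session, net.group, roi,
                         int(k[idx]), float(c[idx]), float(e[idx]), mode))
    return pd.DataFrame(rows, columns=[
        "subject_id", "session", "group", "roi",
        "degree", "clustering", "local_efficiency", "mode",
    ])
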