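"""Per-node centrality measures used as classifier features.

Conventions: degree centrality is the raw degree; betweenness is normalized
by the number of node pairs ``(n-1)(n-2)/2``; closeness is ``(n-1)`` over the
sum of shortest-path distances; eigenvector centrality is the principal
eigenvector of the adjacency matrix rescaled so its maximum entry is exactly
1.  The classifier downstream is invariant to monotone per-feature
transforms, so these conventions matter for determinism, not discrimination.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["compute_centralities"]

CENTRALITY_COLUMNS = ["DC", "BC", "CC", "EC"]


def compute_centralities(net: nx.Graph) -> pd.DataFrame:
    """DC, BC, CC and EC for every node of a connected network.

    Returns a DataFrame indexed by node identifier.  Raises on a
    disconnected network, where closeness is ill-defined.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(net):
        raise ValueError("centralities require a connected network (extract the LCC)")
    nodes = sorted(net.nodes)
    dc = pd.Series(dict(net.degree()), dtype=float)
    bc = pd.Series(nx.betweenness_centrality(net, normalized=True))
    cc = pd.Series(nx.closeness_centrality(net))
    ec = pd.Series(_eigenvector_power(net, nodes))
    out = pd.DataFrame({"DC": dc, "BC": bc, "CC": cc, "EC": ec}).loc[nodes]
    return out


def _eigenvector_power(
    net: nx.Graph, nodes: list, tol: float = 1e-10, max_iter: int = 10000
) -> dict:
    """Principal adjacency eigenvector by power iteration.

    Deterministic (uniform start vector), converged to ``tol`` in the sup
    norm of the normalized iterate, max-scaled to 1.  Chosen over library
    ARPACK routines because their random start vectors make low-order
    digits run-dependent, which would break byte-identical reruns.
    """
    a = nx.to_scipy_sparse_array(net, nodelist=nodes, format="csr", dtype=float)
    x = np.ones(len(nodes))
    x /= np.linalg.norm(x)
    for _ in range(max_iter):
        nxt = a @ x
        nxt /= np.linalg.norm(nxt)
        if np.abs(nxt - x).max() < tol:
            x = nxt
            break
        x = nxt
    x = np.abs(x)
    x /= x.max()
    return dict(zip(nodes, x))
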