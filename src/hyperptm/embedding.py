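"""Hyperbolic embedding of an observed network (LaBNE + HyperMap refinement).

The embedding proceeds in three stages.  Radial coordinates come from the
degree ranking: under a popularity-similarity growth process with target
degree exponent ``gamma``, the node of rank ``k`` (1 = highest degree) sits at
``r_k = 2*beta*ln(k) + 2*(1-beta)*ln(N)`` with ``beta = 1/(gamma-1)``.
Angular coordinates are initialized by Laplacian eigenmaps (LaBNE): the
eigenvectors of the second- and third-smallest eigenvalues of the generalized
problem ``L v = lambda D v`` give a planar layout whose polar angle orders
nodes by similarity.  A maximum-likelihood sweep (HyperMap-style) then refines
each angle locally under the connection model
``p(d) = 1 / (1 + exp((d - R) / (2T)))``.

Angles are only identified up to rotation and reflection; accuracy is
measured with a gauge-invariant circular correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import TWO_PI, hyperbolic_distance

__all__ = [
    "EmbeddedNetwork",
    "assign_radial_coords",
    "labne_angles",
    "hypermap_refine",
    "embed",
    "log_likelihood",
    "circular_correlation",
    "greedy_routing_success",
]

logger = logging.getLogger(__name__)

_P_CLIP = 1e-12  # probability clip keeping log-likelihood finite


@dataclass
class EmbeddedNetwork:
    """A network together with per-node hyperbolic coordinates.

    ``coords`` is indexed by node identifier with columns ``r`` and ``theta``;
    ``gamma``, ``temperature`` and ``w`` record the popularity-similarity
    parameters the coordinates were generated or inferred under.
    """

    net: nx.Graph
    coords: pd.DataFrame
    gamma: float
    temperature: float
    w: float = TWO_PI
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.net.nodes) - set(self.coords.index)
        if missing:
            raise ValueError(f"{len(missing)} nodes lack coordinates")
        th = self.coords["theta"].to_numpy()
        if ((th < 0) | (th >= self.w)).any():
            raise ValueError("theta outside [0, w)")


def _degree_rank(net: nx.Graph) -> list:
    """Nodes sorted by decreasing degree, ties by identifier."""
    return sorted(net.nodes, key=lambda v: (-net.degree(v), v))


def assign_radial_coords(net: nx.Graph, gamma: float, w: float = TWO_PI) -> pd.Series:
    """Radii from the degree ranking: rank k gets ``2b ln k + 2(1-b) ln N``."""
    if gamma <= 2:
        raise ValueError("gamma must exceed 2")
    beta = 1.0 / (gamma - 1.0)
    nodes = _degree_rank(net)
    n = len(nodes)
    ranks = np.arange(1, n + 1, dtype=float)
    radii = 2.0 * beta * np.log(ranks) + 2.0 * (1.0 - beta) * np.log(n)
    return pd.Series(radii, index=nodes, name="r")


def labne_angles(net: nx.Graph, w: float = TWO_PI) -> pd.Series:
    """Laplacian-eigenmap angles in ``[0, w)``.

    Solves ``L v = lambda D v`` through the symmetrically normalized operator
    ``D^{-1/2} A D^{-1/2}`` (sparse for large graphs, dense below 500 nodes)
    and takes the polar angle of the eigenvectors belonging to the second and
    third smallest eigenvalues.
    """
    if net.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes for a planar eigenmap")
    if not nx.is_connected(net):
        raise ValueError("network must be connected; extract the LCC first")
    nodes = sorted(net.nodes)
    a = nx.to_scipy_sparse_array(net, nodelist=nodes, format="csr", dtype=float)
    deg = np.asarray(a.sum(axis=1)).ravel()
    d_isqrt = 1.0 / np.sqrt(deg)
    m = sp.diags(d_isqrt) @ a @ sp.diags(d_isqrt)
    n = len(nodes)
    if n < 500:
        vals, vecs = scipy.linalg.eigh(m.toarray())
        order = np.argsort(vals)[::-1]  # largest of M = smallest of L_sym
        vecs = vecs[:, order[:3]]
    else:
        try:
            # fixed start vector keeps repeated runs bit-identical
            v0 = np.ones(n) / np.sqrt(n)
            vals, vecs = spla.eigsh(m, k=3, which="LA", v0=v0)
            order = np.argsort(vals)[::-1]
            vecs = vecs[:, order]
        except Exception as exc:  # pragma: no cover - solver failure path
            raise RuntimeError(
                "sparse eigen-solver failed; retry with the dense solver "
                "(n < 500) or check the network for pathologies"
            ) from exc
    # generalized eigenvectors of L v = lambda D v
    v2 = d_isqrt * vecs[:, 1]
    v3 = d_isqrt * vecs[:, 2]
    theta = np.mod(np.arctan2(v3, v2), TWO_PI) * (w / TWO_PI)
    theta = np.mod(theta, w)  # guard against theta == w from round-off
    return pd.Series(theta, index=nodes, name="theta")


def log_likelihood(
    net: nx.Graph,
    coords: pd.DataFrame,
    temperature: float,
    w: float = TWO_PI,
    R: float | None = None,
) -> float:
    """Full pairwise log-likelihood of the graph under the connection model.

    Every node pair contributes ``ln p(d)`` if linked and ``ln(1 - p(d))``
    otherwise, with ``p(d) = 1/(1+exp((d-R)/(2T)))`` and ``R`` defaulting to
    the outermost radius.  Quadratic in n; intended for n up to a few
    thousand.
    """
    nodes = list(coords.index)
    r = coords["r"].to_numpy()
    th = coords["theta"].to_numpy()
    if R is None:
        R = float(r.max())
    adj = nx.to_numpy_array(net, nodelist=nodes, dtype=bool)
    total = 0.0
    for i in range(1, len(nodes)):
        d = hyperbolic_distance(r[i], th[i], r[:i], th[:i], w)
        p = np.clip(1.0 / (1.0 + np.exp((d - R) / (2.0 * temperature))), _P_CLIP, 1 - _P_CLIP)
        total += float(np.sum(np.where(adj[i, :i], np.log(p), np.log1p(-p))))
    return total


def hypermap_refine(
    net: nx.Graph,
    radii: pd.Series,
    init_angles: pd.Series,
    gamma: float,
    temperature: float,
    w: float = TWO_PI,
    window: float = np.pi / 6,
    n_candidates: int = 60,
    passes: int = 1,
    nonedge_cap: int = 2000,
    seed: int = 0,
) -> pd.Series:
    """Likelihood refinement of the angles, one local sweep per pass.

    Nodes are visited in decreasing-degree order.  Each node's angle is
    replaced by the best of ``n_candidates`` equally spaced candidates in
    ``[init - window, init + window]`` (the incumbent is always a candidate,
    so the local likelihood never decreases).  The local objective sums
    ``ln p(d)`` over the node's neighbors and ``ln(1-p(d))`` over its
    non-neighbors; with more than ``nonedge_cap`` non-neighbors a seeded
    subsample of that size is used.
    """
    if temperature < 0.01:
        raise ValueError(
            "temperature below 0.01 makes the likelihood degenerate; use T >= 0.01"
        )
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    r = radii.reindex(nodes).to_numpy(dtype=float)
    theta = init_angles.reindex(nodes).to_numpy(dtype=float).copy()
    R = float(r.max())
    rng = np.random.default_rng(seed)
    order = [index[v] for v in _degree_rank(net)]
    neigh = {i: np.array([index[u] for u in net.neighbors(nodes[i])]) for i in order}

    for _ in range(max(passes, 0)):
        for i in order:
            nb = neigh[i]
            others = np.setdiff1d(np.arange(len(nodes)), np.append(nb, i))
            if len(others) > nonedge_cap:
                others = rng.choice(others, size=nonedge_cap, replace=False)
            if window > 0 and n_candidates > 0:
                cand = np.linspace(theta[i] - window, theta[i] + window, n_candidates)
                cand = np.concatenate(([theta[i]], np.mod(cand, w)))
            else:
                cand = np.array([theta[i]])
            idx = np.concatenate((nb, others)).astype(int)
            is_edge = np.zeros(len(idx), dtype=bool)
            is_edge[: len(nb)] = True
            # candidates x partners distance matrix
            d = hyperbolic_distance(
                np.full((len(cand), len(idx)), r[i]),
                np.repeat(cand[:, None], len(idx), axis=1),
                np.broadcast_to(r[idx], (len(cand), len(idx))),
                np.broadcast_to(theta[idx], (len(cand), len(idx))),
                w,
            )
            p = np.clip(
                1.0 / (1.0 + np.exp((d - R) / (2.0 * temperature))), _P_CLIP, 1 - _P_CLIP
            )
            ll = np.where(is_edge[None, :], np.log(p), np.log1p(-p)).sum(axis=1)
            theta[i] = cand[int(np.argmax(ll))]  # first max -> ties keep incumbent
    return pd.Series(np.mod(theta, w), index=nodes, name="theta")


def embed(
    net: nx.Graph,
    gamma: float = 2.97,
    temperature: float = 0.83,
    w: float = TWO_PI,
    refine: bool = True,
    window: float = np.pi / 6,
    n_candidates: int = 60,
    passes: int = 1,
    nonedge_cap: int = 2000,
    seed: int = 0,
) -> EmbeddedNetwork:
    """Full LaBNE + HM embedding of a connected network."""
    if not nx.is_connected(net):
        raise ValueError(
            "embedding requires a connected network; apply "
            "largest_connected_component first"
        )
    radii = assign_radial_coords(net, gamma, w)
    angles = labne_angles(net, w)
    if refine:
        angles = hypermap_refine(
            net,
            radii,
            angles,
            gamma,
            temperature,
            w,
            window=window,
            n_candidates=n_candidates,
            passes=passes,
            nonedge_cap=nonedge_cap,
            seed=seed,
        )
    nodes = sorted(net.nodes)
    coords = pd.DataFrame(
        {"r": radii.reindex(nodes), "theta": angles.reindex(nodes)}, index=nodes
    )
    return EmbeddedNetwork(net=net, coords=coords, gamma=gamma, temperature=temperature, w=w)


# ---------------------------------------------------------------------------
# quality metrics
# ---------------------------------------------------------------------------


def circular_correlation(a, b) -> float:
    """Fisher-Lee circular correlation between two angle samples.

    Invariant to rotations of either sample; a reflection flips the sign, so
    gauge-invariant comparisons should use the absolute value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    abar = np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))
    bbar = np.arctan2(np.mean(np.sin(b)), np.mean(np.cos(b)))
    sa = np.sin(a - abar)
    sb = np.sin(b - bbar)
    denom = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if denom == 0:
        return 0.0
    return float(np.sum(sa * sb) / denom)


def greedy_routing_success(
    emb: EmbeddedNetwork, n_pairs: int = 200, seed: int = 0
) -> float:
    """Fraction of random source-target pairs reached by greedy routing.

    At each hop the packet moves to the neighbor hyperbolically closest to the
    target; delivery fails on a loop (revisiting a node).
    """
    nodes = sorted(emb.net.nodes)
    r = emb.coords["r"]
    th = emb.coords["theta"]
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_pairs):
        s, t = rng.choice(len(nodes), size=2, replace=False)
        src, tgt = nodes[s], nodes[t]
        visited = {src}
        cur = src
        while cur != tgt:
            nbrs = list(emb.net.neighbors(cur))
            d = hyperbolic_distance(
                r[nbrs].to_numpy(), th[nbrs].to_numpy(), r[tgt], th[tgt], emb.w
            )
            nxt = nbrs[int(np.argmin(d))]
            if nxt in visited and nxt != tgt:
                break
            visited.add(nxt)
            cur = nxt
        ok += cur == tgt
    return ok / n_pairs
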