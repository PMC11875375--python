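"""Clustering in the similarity (angular) dimension.

Nodes embedded on the hyperbolic disc agglomerate in angle by function; the
clustering cuts the circle wherever the gap between consecutive sorted angles
exceeds a threshold ``g``, and each arc between cuts becomes a cluster.  A
minimum cluster size is enforced (small sectors are useless for downstream
enrichment-style analyses); :func:`select_gap_size` scans the observed gaps
for the smallest threshold whose clustering honors it.  One level of
subclustering restricted to a single arc is supported.

Gap comparison is strict: a gap must exceed ``g`` to cut, so boundary gaps
exactly equal to ``g`` stay inside a cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import TWO_PI

__all__ = [
    "AngularClusters",
    "ClusterSizeError",
    "circular_gaps",
    "cluster_by_gap",
    "select_gap_size",
    "subcluster",
]


class ClusterSizeError(ValueError):
    """A clustering produced a cluster below the minimum size constraint."""


@dataclass(frozen=True)
class AngularClusters:
    """An ordered partition of nodes into angularly contiguous clusters."""

    clusters: tuple
    gap_size: float
    min_size: int

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> pd.Series:
        """Node -> cluster index (0-based, in angular order)."""
        out = {}
        for lab, members in enumerate(self.clusters):
            for v in members:
                out[v] = lab
        return pd.Series(out, name="cluster")


def _sorted_angles(thetas: pd.Series, w: float) -> tuple[list, np.ndarray]:
    if isinstance(thetas, dict):
        thetas = pd.Series(thetas)
    th = thetas.astype(float)
    if ((th < 0) | (th >= w)).any():
        raise ValueError(f"angles must lie in [0, {w})")
    # stable sort: duplicate angles keep node-id order
    df = pd.DataFrame({"node": th.index, "theta": th.to_numpy()})
    df = df.sort_values(["theta", "node"], kind="stable")
    return df["node"].tolist(), df["theta"].to_numpy()


def circular_gaps(thetas: pd.Series, w: float = TWO_PI) -> np.ndarray:
    """Gaps between consecutive sorted angles, wrap-around gap last.

    For ``n`` angles returns ``n`` gaps summing to ``w``: ``gap[i]`` follows
    the ``i``-th sorted angle, and ``gap[n-1] = w - (max - min)`` closes the
    circle.
    """
    _, th = _sorted_angles(thetas, w)
    if len(th) < 2:
        raise ValueError("need at least 2 angles to form gaps")
    return np.append(np.diff(th), w - (th[-1] - th[0]))


def cluster_by_gap(
    thetas: pd.Series, g: float, min_size: int = 3, w: float = TWO_PI
) -> AngularClusters:
    """Cut the circle at every gap strictly greater than ``g``.

    Raises :class:`ClusterSizeError` if any resulting cluster holds fewer
    than ``min_size`` nodes (pick ``g`` with :func:`select_gap_size` in that
    case).  With no gap above ``g`` all nodes form a single cluster.
    """
    if g <= 0:
        raise ValueError("gap threshold must be positive")
    nodes, th = _sorted_angles(thetas, w)
    n = len(nodes)
    if n < 2:
        clusters = (tuple(nodes),)
        return AngularClusters(clusters, g, min_size)
    gaps = np.append(np.diff(th), w - (th[-1] - th[0]))
    cuts = np.flatnonzero(gaps > g)  # cluster boundary after sorted index i
    if len(cuts) == 0:
        clusters = [list(nodes)]
    else:
        # arcs between cuts; the first cluster starts just after the last cut
        clusters = []
        cutset = set(cuts.tolist())
        idx = (int(cuts[-1]) + 1) % n
        current = []
        for _ in range(n):
            current.append(nodes[idx])
            if idx in cutset:
                clusters.append(current)
                current = []
            idx = (idx + 1) % n
        if current:
            clusters.append(current)
    small = [len(c) for c in clusters if len(c) < min_size]
    if small:
        raise ClusterSizeError(
            f"gap {g} yields {len(small)} clusters below min size {min_size}"
        )
    return AngularClusters(tuple(tuple(c) for c in clusters), g, min_size)


def select_gap_size(
    thetas: pd.Series, min_size: int = 3, w: float = TWO_PI
) -> float:
    """Smallest observed gap value usable as threshold under the size constraint.

    Candidate thresholds are the observed gap values; smaller ``g`` means
    more clusters, so the smallest valid candidate maximizes resolution.  The
    largest gap is always valid (single cluster) when ``n >= min_size``.
    """
    if len(thetas) < min_size:
        raise ValueError("fewer nodes than the minimum cluster size")
    gaps = circular_gaps(thetas, w)
    for g in np.unique(gaps):
        try:
            cluster_by_gap(thetas, float(g), min_size, w)
        except ClusterSizeError:
            continue
        return float(g)
    raise AssertionError("unreachable: the largest gap is always a valid threshold")


def subcluster(
    members, thetas: pd.Series, g2: float, min_size2: int = 5, w: float = TWO_PI
) -> AngularClusters:
    """Re-cluster one angularly contiguous cluster with a finer gap size.

    Inside an arc there is no wrap-around gap: only the internal consecutive
    differences can cut.
    """
    if g2 <= 0:
        raise ValueError("gap threshold must be positive")
    sub = thetas.loc[list(members)]
    nodes, th = _sorted_angles(sub, w)
    n = len(nodes)
    if n < 2:
        return AngularClusters((tuple(nodes),), g2, min_size2)
    internal = np.diff(th)
    cuts = np.flatnonzero(internal > g2)
    clusters = []
    start = 0
    for c in cuts:
        clusters.append(tuple(nodes[start : c + 1]))
        start = c + 1
    clusters.append(tuple(nodes[start:]))
    small = [c for c in clusters if len(c) < min_size2]
    if small:
        raise ClusterSizeError(
            f"gap {g2} yields {len(small)} subclusters below min size {min_size2}"
        )
    return AngularClusters(tuple(clusters), g2, min_size2)
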