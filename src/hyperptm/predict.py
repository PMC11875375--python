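"""Proteome-wide bidirectional edge scoring.

Every undirected edge is scored twice — once per orientation, with the first
protein playing effector and the second target — so a network with |E| edges
yields exactly 2|E| prediction records.  The two orientations share their
edge-level features but swap the node blocks, and their scores are not forced
to be complementary: both directions of a genuine mutual interaction can
legitimately score high.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .geometry import TWO_PI
from .model import TrainedModel, feature_matrix
from .training import LabeledPair

__all__ = ["score_all_edges", "threshold_counts", "query_protein"]

logger = logging.getLogger(__name__)


def score_all_edges(
    model: TrainedModel,
    net: nx.Graph,
    node_table: pd.DataFrame,
    w: float = TWO_PI,
    threshold: float = 0.5,
    chunk_size: int = 20000,
) -> pd.DataFrame:
    """Score both orientations of every edge.

    Returns a DataFrame with columns ``p1`` (tested as effector), ``p2``
    (tested as target), ``score`` and ``predicted_class``, sorted by
    (p1, p2).  Scoring streams in chunks so large networks never hold all
    per-tree votes at once.
    """
    directed: list[tuple[str, str]] = []
    for a, b in sorted(map(tuple, map(sorted, net.edges()))):
        directed.append((a, b))
        directed.append((b, a))
    frames = []
    for start in range(0, len(directed), chunk_size):
        chunk = directed[start : start + chunk_size]
        pairs = [LabeledPair(e, t, False) for e, t in chunk]
        X, _ = feature_matrix(pairs, node_table, w)
        scores = model.predict_proba(X)
        frames.append(
            pd.DataFrame(
                {
                    "p1": [e for e, _ in chunk],
                    "p2": [t for _, t in chunk],
                    "score": scores,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["p1", "p2", "score"]
    )
    out["predicted_class"] = out["score"] >= threshold
    out = out.sort_values(["p1", "p2"], kind="stable", ignore_index=True)
    return out


def threshold_counts(records: pd.DataFrame, thresholds) -> dict[float, int]:
    """Number of records with score >= t, for each threshold t."""
    scores = records["score"].to_numpy()
    return {float(t): int(np.sum(scores >= t)) for t in thresholds}


def query_protein(
    records: pd.DataFrame, protein: str, role: str = "effector", min_score: float = 0.0
) -> pd.DataFrame:
    """Predictions involving ``protein`` in the requested role, best first.

    ``role`` is ``"effector"`` (protein is p1) or ``"target"`` (protein is
    p2).  Unknown proteins yield an empty frame with a warning.
    """
    if role not in ("effector", "target"):
        raise ValueError("role must be 'effector' or 'target'")
    col = "p1" if role == "effector" else "p2"
    hits = records[(records[col] == protein) & (records["score"] >= min_score)]
    if hits.empty and protein not in set(records["p1"]) | set(records["p2"]):
        logger.warning("protein %s absent from the prediction table", protein)
    return hits.sort_values("score", ascending=False, kind="stable", ignore_index=True)
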