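"""Construction of the directed training set.

Positives come from interactions annotated as phosphorylation (PSI-MI
MI:0217) or dephosphorylation (MI:0203) whose direction can be resolved from
effector catalogs: if exactly one endpoint is a kinase or phosphatase the
pair is oriented effector -> target; if one endpoint is a kinase and the
other a phosphatase both orientations are emitted (mutual action); pairs
where neither endpoint is an effector, both are the same effector type, or an
endpoint's type is ambiguous (present in both catalogs) are discarded —
their direction cannot be established.  Negatives are the remaining directed
orientations of network edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "EffectorCatalog",
    "LabeledPair",
    "PTM_CODES",
    "load_catalog",
    "load_ptm_annotations",
    "build_directed_positives",
    "build_negatives",
]

logger = logging.getLogger(__name__)

PTM_CODES = frozenset({"MI:0217", "MI:0203"})


@dataclass(frozen=True)
class EffectorCatalog:
    """Kinase and phosphatase identifier sets (may overlap)."""

    kinases: frozenset
    phosphatases: frozenset

    def type_of(self, protein: str) -> str:
        """'kinase', 'phosphatase', 'ambiguous' (both) or 'none'."""
        k = protein in self.kinases
        p = protein in self.phosphatases
        if k and p:
            return "ambiguous"
        if k:
            return "kinase"
        if p:
            return "phosphatase"
        return "none"


@dataclass(frozen=True)
class LabeledPair:
    """A directed (effector, target) pair with its label."""

    effector: str
    target: str
    label: bool
    effector_type: str = "unknown"

    def __post_init__(self) -> None:
        if self.effector == self.target:
            raise ValueError("self-pairs are not allowed")


def load_catalog(kinase_path: str | Path, phosphatase_path: str | Path) -> EffectorCatalog:
    """Read one-identifier-per-line kinase and phosphatase catalogs."""

    def read_ids(path):
        with open(path, encoding="utf-8") as fh:
            return frozenset(line.strip() for line in fh if line.strip())

    return EffectorCatalog(read_ids(kinase_path), read_ids(phosphatase_path))


def load_ptm_annotations(
    path: str | Path, codes: frozenset = PTM_CODES
) -> set[frozenset]:
    """Unordered protein pairs annotated with an accepted PSI-MI code.

    Expects a TSV with columns ``id_a``, ``id_b``, ``psimi_code``.  Rows with
    other codes are skipped with a warning; duplicates collapse.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in ("id_a", "id_b", "psimi_code") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation table missing columns {missing}")
    keep = df["psimi_code"].isin(codes)
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.warning("%s: skipped %d rows with codes outside %s", path, n_skipped, sorted(codes))
    pairs = {
        frozenset((a, b))
        for a, b in zip(df.loc[keep, "id_a"], df.loc[keep, "id_b"])
        if a != b
    }
    return pairs


def build_directed_positives(
    ptm_pairs: Iterable, catalog: EffectorCatalog, net: nx.Graph | None = None
) -> list[LabeledPair]:
    """Resolve annotated pairs into directed positives.

    When ``net`` is given, pairs that are not network edges are dropped and
    the count logged — features only exist for edges of the embedded network.
    """
    positives: list[LabeledPair] = []
    n_not_edge = 0
    for pair in sorted(tuple(sorted(p)) for p in ptm_pairs):
        a, b = pair
        if net is not None and not net.has_edge(a, b):
            n_not_edge += 1
            continue
        ta, tb = catalog.type_of(a), catalog.type_of(b)
        if "ambiguous" in (ta, tb):
            continue
        if ta == "none" and tb == "none":
            continue
        if ta == tb:  # both kinases or both phosphatases: direction unknown
            continue
        if ta != "none" and tb != "none":
            # kinase vs phosphatase: mutual action, both orientations
            positives.append(LabeledPair(a, b, True, ta))
            positives.append(LabeledPair(b, a, True, tb))
        elif ta != "none":
            positives.append(LabeledPair(a, b, True, ta))
        else:
            positives.append(LabeledPair(b, a, True, tb))
    if n_not_edge:
        logger.info("dropped %d annotated pairs absent from the network", n_not_edge)
    return positives


def build_negatives(
    net: nx.Graph,
    positives: Iterable[LabeledPair],
    seed: int = 0,
    size: int | None = None,
    exclude_reverse: bool = True,
) -> list[LabeledPair]:
    """Directed orientations of network edges that are not positives.

    By default the reverse orientation of each positive is also excluded:
    its true label is unknown (the unannotated direction of a genuine
    phospho-interaction may well be active too).  ``exclude_reverse=False``
    restores the literal everything-but-the-positives pool.  With ``size``
    a seeded subsample of that many negatives is returned; otherwise the
    full pool, deterministically ordered.
    """
    pos = {(p.effector, p.target) for p in positives}
    banned = set(pos)
    if exclude_reverse:
        banned |= {(t, e) for e, t in pos}
    pool = []
    for a, b in sorted(map(tuple, map(sorted, net.edges()))):
        for d in ((a, b), (b, a)):
            if d not in banned:
                pool.append(d)
    if size is not None:
        if size > len(pool):
            raise ValueError(f"requested {size} negatives, pool holds {len(pool)}")
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pool), size=size, replace=False)
        pool = [pool[i] for i in sorted(idx)]
    return [LabeledPair(e, t, False) for e, t in pool]
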