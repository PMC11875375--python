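"""Tabular I/O for interaction networks and the pipeline's derived tables.

Reads scored edge lists (either a generic three-column TSV or the six-column
HIPPIE download dialect), applies the confidence filter, extracts the largest
connected component, and round-trips the node / training / prediction tables
that the rest of the pipeline exchanges.  All files are UTF-8, tab-separated,
with a header row; lines starting with ``#`` are provenance comments and are
ignored on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "EdgeListDialect",
    "GENERIC_DIALECT",
    "HIPPIE_DIALECT",
    "InteractionRecord",
    "FormatError",
    "RowError",
    "read_interactions",
    "build_network",
    "largest_connected_component",
    "write_table",
    "write_node_table",
    "read_node_table",
    "write_edge_table",
    "write_training_table",
    "read_training_table",
    "write_predictions",
    "read_predictions",
]

NODE_COLUMNS = ["id", "r", "theta", "DC", "BC", "CC", "EC"]
_FLOAT_FMT = "%.15g"  # round-trips well beyond 12 significant digits


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class RowError(ValueError):
    """One or more data rows could not be parsed; lists the line numbers."""

    def __init__(self, problems: Sequence[tuple[int, str]]):
        self.problems = list(problems)
        lines = "; ".join(f"line {n}: {msg}" for n, msg in self.problems)
        super().__init__(f"unparseable rows: {lines}")


@dataclass(frozen=True)
class EdgeListDialect:
    """Column positions of the two protein identifiers and the score.

    The HIPPIE download carries (ID-A, alt-ID-A, ID-B, alt-ID-B, score,
    evidence); a generic edge list is just (ID-A, ID-B, score).
    """

    id_a: int = 0
    id_b: int = 1
    score: int = 2
    sep: str = "\t"
    header: bool = True


GENERIC_DIALECT = EdgeListDialect()
HIPPIE_DIALECT = EdgeListDialect(id_a=0, id_b=2, score=4)


@dataclass(frozen=True)
class InteractionRecord:
    protein_a: str
    protein_b: str
    confidence: float

    def __post_init__(self) -> None:
        if not self.protein_a or not self.protein_b:
            raise ValueError("protein identifiers must be non-empty")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


def read_interactions(
    path: str | Path, dialect: EdgeListDialect = GENERIC_DIALECT
) -> list[InteractionRecord]:
    """Parse a scored edge list into interaction records.

    Raises :class:`FormatError` if a row is too short to contain the score
    column, and :class:`RowError` (listing 1-based line numbers) if scores
    fail to parse as floats in [0, 1].
    """
    records: list[InteractionRecord] = []
    problems: list[tuple[int, str]] = []
    min_width = max(dialect.id_a, dialect.id_b, dialect.score) + 1
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if dialect.header and lineno == 1:
                continue
            fields = line.split(dialect.sep)
            if len(fields) < min_width:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} columns, "
                    f"score column {dialect.score} missing"
                )
            try:
                score = float(fields[dialect.score])
                records.append(
                    InteractionRecord(fields[dialect.id_a], fields[dialect.id_b], score)
                )
            except ValueError as exc:
                problems.append((lineno, str(exc)))
    if problems:
        raise RowError(problems)
    return records


def build_network(
    records: Iterable[InteractionRecord], min_confidence: float = 0.71
) -> nx.Graph:
    """Confidence-filtered simple graph: keep records with score >= threshold,
    drop self-interactions, collapse duplicate pairs in either orientation
    (retaining the maximum confidence seen)."""
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError("min_confidence must lie in [0, 1]")
    g = nx.Graph()
    for rec in records:
        if rec.confidence < min_confidence or rec.protein_a == rec.protein_b:
            continue
        a, b = sorted((rec.protein_a, rec.protein_b))
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], rec.confidence)
        else:
            g.add_edge(a, b, confidence=rec.confidence)
    return g


def largest_connected_component(net: nx.Graph) -> nx.Graph:
    """Subgraph induced by the largest component.

    Ties on size are broken by the lexicographically smallest sorted tuple of
    node identifiers, so the result is deterministic.
    """
    if net.number_of_nodes() == 0:
        return nx.Graph()
    components = [tuple(sorted(c)) for c in nx.connected_components(net)]
    max_size = max(len(c) for c in components)
    best = min(c for c in components if len(c) == max_size)
    return net.subgraph(best).copy()


# ---------------------------------------------------------------------------
# node / edge / training / prediction tables
# ---------------------------------------------------------------------------


def _write_with_comments(df: pd.DataFrame, path: str | Path, comments: Sequence[str]):
    with open(path, "w", encoding="utf-8") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def write_table(df: pd.DataFrame, path: str | Path, comments: Sequence[str] = ()) -> None:
    """Write any tab-separated table with provenance comment lines."""
    _write_with_comments(df, path, comments)


def write_node_table(
    table: pd.DataFrame, path: str | Path, comments: Sequence[str] = ()
) -> None:
    """Write the per-node table (id, r, theta, DC, BC, CC, EC)."""
    missing = [c for c in NODE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"node table missing columns {missing}")
    _write_with_comments(table[NODE_COLUMNS], path, comments)


def read_node_table(path: str | Path, w: float = 2.0 * np.pi) -> pd.DataFrame:
    """Read a node table, validating the angular-span invariant ``theta < w``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    missing = [c for c in NODE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: node table missing columns {missing}")
    if ((df["theta"] < 0) | (df["theta"] >= w)).any():
        bad = df.loc[(df["theta"] < 0) | (df["theta"] >= w), "id"].tolist()[:5]
        raise FormatError(f"{path}: theta outside [0, {w}) for nodes {bad}")
    if (df["r"] < 0).any():
        raise FormatError(f"{path}: negative radii present")
    return df[NODE_COLUMNS]


def write_edge_table(
    df: pd.DataFrame, path: str | Path, comments: Sequence[str] = ()
) -> None:
    """Write the per-edge table (p1, p2, hyp_dist, r_abs_diff)."""
    cols = ["p1", "p2", "hyp_dist", "r_abs_diff"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"edge table missing columns {missing}")
    _write_with_comments(df[cols], path, comments)


def write_training_table(
    pairs: pd.DataFrame, path: str | Path, comments: Sequence[str] = ()
) -> None:
    """Write labeled directed pairs (p1 = effector, effector_type, p2 = target)."""
    cols = ["p1", "effector_type", "p2"]
    missing = [c for c in cols if c not in pairs.columns]
    if missing:
        raise FormatError(f"training table missing columns {missing}")
    _write_with_comments(pairs[cols], path, comments)


def read_training_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in ("p1", "effector_type", "p2") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: training table missing columns {missing}")
    return df


def write_predictions(
    df: pd.DataFrame, path: str | Path, comments: Sequence[str] = ()
) -> None:
    """Write the directed prediction table (p1, p2, score, predicted_class)."""
    cols = ["p1", "p2", "score", "predicted_class"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"prediction table missing columns {missing}")
    _write_with_comments(df[cols], path, comments)


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", dtype={"p1": str, "p2": str, "score": float}
    )
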