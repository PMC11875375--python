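"""Synthetic networks and annotations from the popularity-similarity model.

Grows a network on the hyperbolic disc: node ``i`` appears at radius
``2 ln i`` and a uniform random angle, all earlier nodes drift outward
(popularity fading, ``r_j(i) = 2*beta*ln j + 2*(1-beta)*ln i`` with
``beta = 1/(gamma-1)``), and the newcomer links to ``m`` existing nodes —
the hyperbolically closest ones at temperature ``T = 0``, or a random set
drawn through the connection probability
``p(d) = 1/(1+exp((d - R_i)/(2T)))`` at ``T > 0``.  Lower temperature yields
stronger clustering; ``gamma`` sets the degree-distribution tail.

On top of a generated network the module plants what a curated
phospho-interaction corpus would provide: kinase and phosphatase catalogs
concentrated in angular sectors (mirroring the empirical concentration of
effectors in the similarity dimension) and directed effector-to-target
positive pairs biased toward short hyperbolic distances.  Everything is
reproducible from a single integer seed, and writers emit the same file
formats the real-data pipeline consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .embedding import EmbeddedNetwork
from .geometry import TWO_PI, angular_separation, hyperbolic_distance

__all__ = [
    "PSParams",
    "PlantedAnnotation",
    "generate_ps_network",
    "plant_effectors",
    "plant_positive_pairs",
    "fit_degree_exponent",
    "write_synthetic_inputs",
]

logger = logging.getLogger(__name__)

_MAX_SWEEPS = 50  # Bernoulli sweeps before falling back to closest fill


@dataclass(frozen=True)
class PSParams:
    """Popularity-similarity growth parameters.

    ``n`` nodes join one at a time, each bringing ``m`` links.  ``gamma > 2``
    is the target degree exponent (``beta = 1/(gamma-1)`` is the fading
    exponent), ``temperature`` in ``[0, 1)`` controls clustering strength,
    and ``w`` is the angular span of the disc.
    """

    n: int
    m: int = 2
    gamma: float = 2.5
    temperature: float = 0.3
    w: float = TWO_PI
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < self.m + 1:
            raise ValueError(f"need n >= m+1, got n={self.n}, m={self.m}")
        if self.gamma <= 2:
            raise ValueError("gamma must exceed 2")
        if not 0.0 <= self.temperature < 1.0:
            raise ValueError("temperature must lie in [0, 1)")
        if self.m < 1:
            raise ValueError("m must be positive")

    @property
    def beta(self) -> float:
        return 1.0 / (self.gamma - 1.0)


@dataclass(frozen=True)
class PlantedAnnotation:
    """Planted effector catalogs and directed positive pairs.

    ``positive_pairs`` rows are ``(effector, target, effector_type)`` and
    every pair is an edge of the generating network.
    """

    kinases: frozenset = frozenset()
    phosphatases: frozenset = frozenset()
    positive_pairs: tuple = ()

    @property
    def effectors(self) -> frozenset:
        return self.kinases | self.phosphatases


def _node_name(i: int) -> str:
    # zero-padded so lexicographic order equals arrival order
    return f"P{i:06d}"


def _disc_radius(i: int, params: PSParams) -> float:
    """Connection-radius calibration R_i making the expected in-sweep degree m."""
    t, beta, m = params.temperature, params.beta, params.m
    ri = 2.0 * np.log(i)
    inner = (2.0 * t / np.sin(np.pi * t)) * (1.0 - i ** (-(1.0 - beta))) / (m * (1.0 - beta))
    return ri - 2.0 * np.log(inner)


def generate_ps_network(params: PSParams) -> tuple[EmbeddedNetwork, None] | EmbeddedNetwork:
    """Grow a popularity-similarity network with ground-truth coordinates.

    Returns an :class:`EmbeddedNetwork` whose coordinates are the final,
    post-fading positions.  At ``T = 0`` attachment is deterministic
    (hyperbolically closest nodes) and the edge count equals
    ``sum_i min(i-1, m)`` exactly.
    """
    rng = np.random.default_rng(params.seed)
    n, m, beta, w = params.n, params.m, params.beta, params.w
    theta = rng.uniform(0.0, w, size=n)  # theta[i-1] belongs to node i
    arrival = np.arange(1, n + 1, dtype=float)
    edges: list[tuple[int, int]] = []

    for i in range(2, n + 1):
        k = min(i - 1, m)
        ri = 2.0 * np.log(i)
        # radii of earlier nodes after fading toward the newcomer's epoch
        r_exist = 2.0 * beta * np.log(arrival[: i - 1]) + 2.0 * (1.0 - beta) * np.log(i)
        d = np.atleast_1d(
            hyperbolic_distance(ri, theta[i - 1], r_exist, theta[: i - 1], w)
        )
        if k == i - 1:
            chosen = list(range(i - 1))
        elif params.temperature == 0.0:
            # deterministic closest-m; ties by arrival order via stable sort
            chosen = list(np.argsort(d, kind="stable")[:k])
        else:
            radius = _disc_radius(i, params)
            p = 1.0 / (1.0 + np.exp((d - radius) / (2.0 * params.temperature)))
            linked = np.zeros(i - 1, dtype=bool)
            for _ in range(_MAX_SWEEPS):
                if linked.sum() >= k:
                    break
                u = rng.random(i - 1)
                accept = np.flatnonzero((u < p) & ~linked)
                room = k - int(linked.sum())
                linked[accept[:room]] = True
            if linked.sum() < k:  # rare at sane parameters; fill with closest
                order = np.argsort(d, kind="stable")
                for j in order:
                    if linked.sum() >= k:
                        break
                    linked[j] = True
            chosen = list(np.flatnonzero(linked))
        edges.extend((j + 1, i) for j in chosen)

    net = nx.Graph()
    net.add_nodes_from(_node_name(i) for i in range(1, n + 1))
    net.add_edges_from((_node_name(a), _node_name(b)) for a, b in edges)
    final_r = 2.0 * beta * np.log(arrival) + 2.0 * (1.0 - beta) * np.log(n)
    coords = pd.DataFrame(
        {"r": final_r, "theta": theta}, index=[_node_name(i) for i in range(1, n + 1)]
    ).sort_index()
    return EmbeddedNetwork(
        net=net,
        coords=coords,
        gamma=params.gamma,
        temperature=params.temperature,
        w=w,
        meta={"generator": "ps", "params": params},
    )


def _draw_sector(
    coords: pd.DataFrame,
    k: int,
    center: float,
    spread: float,
    w: float,
    rng: np.random.Generator,
    exclude: set,
) -> list:
    """Draw k nodes concentrated around ``center``; nearest-by-angle fill if
    the sector holds fewer than k eligible nodes."""
    pool = coords.index[~coords.index.isin(list(exclude))]
    sep = pd.Series(
        angular_separation(coords.loc[pool, "theta"].to_numpy(), center, w), index=pool
    )
    in_sector = sep.index[sep < spread]
    if len(in_sector) >= k:
        return list(rng.choice(np.sort(in_sector.to_numpy()), size=k, replace=False))
    logger.warning(
        "sector around %.3f holds %d nodes, %d requested; filling with nearest",
        center,
        len(in_sector),
        k,
    )
    ranked = sep.sort_values(kind="stable").index  # ties resolved by node id order
    return list(ranked[:k])


def plant_effectors(
    emb: EmbeddedNetwork,
    kinase_fraction: float = 0.03,
    phosphatase_fraction: float = 0.015,
    kinase_center: float = 1.8,
    phosphatase_center: float = 4.0,
    spread: float = 0.3,
    mode: str = "two-sector",
    allow_overlap: bool = False,
    seed: int = 0,
) -> PlantedAnnotation:
    """Plant kinase and phosphatase catalogs in angular sectors.

    In ``two-sector`` mode kinases concentrate around ``kinase_center`` and
    phosphatases around ``phosphatase_center`` (emulating the angular
    concentration of real effectors in the similarity dimension);
    ``uniform`` mode ignores the centers and samples uniformly.
    """
    if not 0.0 < kinase_fraction < 1.0 or not 0.0 < phosphatase_fraction < 1.0:
        raise ValueError("effector fractions must lie in (0, 1)")
    if mode not in ("two-sector", "uniform"):
        raise ValueError(f"unknown planting mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = len(emb.coords)
    n_kin = max(1, round(kinase_fraction * n))
    n_pho = max(1, round(phosphatase_fraction * n))
    if mode == "uniform":
        spread_eff = emb.w / 2.0 + 1.0  # sector covers the whole circle
    else:
        spread_eff = spread
    kinases = _draw_sector(
        emb.coords, n_kin, kinase_center, spread_eff, emb.w, rng, exclude=set()
    )
    exclude = set() if allow_overlap else set(kinases)
    phosphatases = _draw_sector(
        emb.coords, n_pho, phosphatase_center, spread_eff, emb.w, rng, exclude=exclude
    )
    return PlantedAnnotation(
        kinases=frozenset(kinases), phosphatases=frozenset(phosphatases)
    )


def plant_positive_pairs(
    emb: EmbeddedNetwork,
    annotation: PlantedAnnotation,
    n_pos: int,
    lam: float = 1.0,
    seed: int = 0,
) -> PlantedAnnotation:
    """Sample directed positive pairs from effector-incident edges.

    Candidates are edges with exactly one effector endpoint, oriented
    effector -> target; they are drawn without replacement with weight
    ``exp(-d/lam)``, favoring hyperbolically close pairs the way real
    phospho-interactions sit closer than background edges.
    """
    eff = annotation.effectors
    candidates: list[tuple[str, str, str]] = []
    dists: list[float] = []
    r = emb.coords["r"]
    th = emb.coords["theta"]
    for a, b in sorted(map(tuple, map(sorted, emb.net.edges()))):
        a_eff, b_eff = a in eff, b in eff
        if a_eff == b_eff:
            continue
        e, t = (a, b) if a_eff else (b, a)
        etype = "kinase" if e in annotation.kinases else "phosphatase"
        candidates.append((e, t, etype))
        dists.append(hyperbolic_distance(r[e], th[e], r[t], th[t], emb.w))
    if n_pos > len(candidates):
        raise ValueError(
            f"requested {n_pos} positives but only {len(candidates)} "
            "effector-incident edges exist"
        )
    if n_pos == 0:
        return replace(annotation, positive_pairs=())
    rng = np.random.default_rng(seed)
    weights = np.exp(-np.asarray(dists) / lam)
    weights /= weights.sum()
    idx = rng.choice(len(candidates), size=n_pos, replace=False, p=weights)
    pairs = tuple(candidates[i] for i in sorted(idx))
    return replace(annotation, positive_pairs=pairs)


def fit_degree_exponent(degrees, kmin: int | None = None) -> float:
    """Maximum-likelihood tail exponent of a degree sample.

    Discrete power-law estimator ``1 + n / sum(ln(k/(kmin - 1/2)))`` over
    degrees ``>= kmin``; ``kmin`` defaults to 5.
    """
    k = np.asarray(degrees, dtype=float)
    if kmin is None:
        kmin = 5
    tail = k[k >= kmin]
    if len(tail) < 10:
        raise ValueError("too few tail observations for a stable fit")
    return float(1.0 + len(tail) / np.sum(np.log(tail / (kmin - 0.5))))


def write_synthetic_inputs(
    emb: EmbeddedNetwork,
    annotation: PlantedAnnotation,
    outdir: str | Path,
    seed: int = 0,
) -> dict[str, Path]:
    """Write generator output in the raw-input formats the pipeline reads.

    Produces a scored edge list (confidences drawn uniformly in
    [0.72, 0.99], i.e. above the default high-confidence cutoff), one-ID-per
    -line kinase and phosphatase catalogs, and a PSI-MI-style annotation
    table tagging kinase pairs MI:0217 and phosphatase pairs MI:0203.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    edges = sorted(map(tuple, map(sorted, emb.net.edges())))
    conf = rng.uniform(0.72, 0.99, size=len(edges))
    paths = {
        "edges": outdir / "edges.tsv",
        "kinases": outdir / "kinases.txt",
        "phosphatases": outdir / "phosphatases.txt",
        "ptm": outdir / "ptm_annotations.tsv",
    }
    with open(paths["edges"], "w", encoding="utf-8") as fh:
        fh.write("id_a\tid_b\tscore\n")
        for (a, b), c in zip(edges, conf):
            fh.write(f"{a}\t{b}\t{c:.4f}\n")
    for key, ids in (("kinases", annotation.kinases), ("phosphatases", annotation.phosphatases)):
        with open(paths[key], "w", encoding="utf-8") as fh:
            for v in sorted(ids):
                fh.write(f"{v}\n")
    with open(paths["ptm"], "w", encoding="utf-8") as fh:
        fh.write("id_a\tid_b\tpsimi_code\n")
        for e, t, etype in annotation.positive_pairs:
            code = "MI:0217" if etype == "kinase" else "MI:0203"
            fh.write(f"{e}\t{t}\t{code}\n")
    return paths
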