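"""End-to-end orchestration: files in, scored predictions out.

Stages: confidence filter -> largest connected component -> hyperbolic
embedding -> centralities -> angular clustering -> directed training-set
construction -> under-sampled cross-validated random forest -> evaluation ->
bidirectional scoring of every edge.  Each stage logs its node/edge counts,
and every output table carries the configuration hash and seed in a
provenance header.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as clu
from . import io as net_io
from . import model as rf
from . import predict as pred
from . import training as tr
from .centrality import compute_centralities
from .config import PipelineConfig
from .embedding import embed
from .synthetic import (
    PSParams,
    generate_ps_network,
    plant_effectors,
    plant_positive_pairs,
    write_synthetic_inputs,
)

__all__ = ["run_pipeline", "prepare_demo_inputs"]

logger = logging.getLogger(__name__)


def prepare_demo_inputs(
    outdir: str | Path,
    n: int = 1000,
    m: int = 4,
    gamma: float = 2.5,
    temperature: float = 0.3,
    n_pos: int = 150,
    spread: float = 0.3,
    lam: float = 1.0,
    seed: int = 0,
) -> dict[str, Path]:
    """Generate a planted synthetic study and write it in raw-input formats.

    Also writes the ground-truth coordinates (``true_coords.tsv``) so demo
    runs can report embedding accuracy.
    """
    outdir = Path(outdir)
    params = PSParams(n=n, m=m, gamma=gamma, temperature=temperature, seed=seed)
    emb = generate_ps_network(params)
    annot = plant_effectors(emb, spread=spread, seed=seed + 1)
    annot = plant_positive_pairs(emb, annot, n_pos=n_pos, lam=lam, seed=seed + 2)
    paths = write_synthetic_inputs(emb, annot, outdir, seed=seed + 3)
    truth = emb.coords.rename_axis("id").reset_index()
    truth_path = outdir / "true_coords.tsv"
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.15g")
    paths["true_coords"] = truth_path
    return paths


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write all artifacts under ``outdir``.

    Returns the run summary (also written to ``run_summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key in ("edges_path", "kinases_path", "phosphatases_path", "ptm_path"):
        path = getattr(config, key)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"configuration {key} missing or absent: {path}")
    provenance = [f"config_hash={config.config_hash()}", f"seed={config.seed}"]
    logger.info("resolved configuration: %s", config.to_dict())
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    # --- network construction -------------------------------------------------
    records = net_io.read_interactions(config.edges_path)
    net = net_io.build_network(records, config.min_confidence)
    logger.info(
        "confidence filter >= %.2f: %d nodes / %d edges",
        config.min_confidence,
        net.number_of_nodes(),
        net.number_of_edges(),
    )
    lcc = net_io.largest_connected_component(net)
    logger.info("LCC: %d nodes / %d edges", lcc.number_of_nodes(), lcc.number_of_edges())
    summary["n_nodes"] = lcc.number_of_nodes()
    summary["n_edges"] = lcc.number_of_edges()

    # --- embedding + centralities --------------------------------------------
    emb = embed(
        lcc,
        gamma=config.gamma,
        temperature=config.temperature,
        w=config.angular_span,
        refine=config.refine,
        window=config.refine_window,
        n_candidates=config.refine_candidates,
        passes=config.refine_passes,
        nonedge_cap=config.nonedge_cap,
        seed=config.seed,
    )
    cent = compute_centralities(lcc)
    node_table = (
        emb.coords.join(cent).rename_axis("id").reset_index()
    )
    net_io.write_node_table(node_table, outdir / "nodes.tsv", provenance)

    # --- angular clustering ---------------------------------------------------
    thetas = emb.coords["theta"]
    g = config.gap_size
    if g is None:
        g = clu.select_gap_size(thetas, config.cluster_min_size, config.angular_span)
        logger.info("auto-selected gap size g=%.6g", g)
    clusters = clu.cluster_by_gap(thetas, g, config.cluster_min_size, config.angular_span)
    labels = clusters.labels().rename("cluster")
    sub_labels = pd.Series(-1, index=labels.index, name="subcluster")
    try:
        sub = clu.subcluster(
            clusters.clusters[0],
            thetas,
            config.subgap_size,
            config.subcluster_min_size,
            config.angular_span,
        )
        for lab, members in enumerate(sub.clusters):
            sub_labels.loc[list(members)] = lab
    except clu.ClusterSizeError as exc:
        logger.warning("subclustering of the first sector skipped: %s", exc)
    cluster_df = pd.DataFrame(
        {"id": labels.index, "cluster": labels.to_numpy(), "subcluster": sub_labels.to_numpy()}
    ).sort_values("id", ignore_index=True)
    net_io.write_table(cluster_df, outdir / "clusters.tsv", provenance)
    summary["gap_size"] = float(g)
    summary["n_clusters"] = clusters.n_clusters

    # --- training set ---------------------------------------------------------
    catalog = tr.load_catalog(config.kinases_path, config.phosphatases_path)
    ptm_pairs = tr.load_ptm_annotations(config.ptm_path)
    positives = tr.build_directed_positives(ptm_pairs, catalog, net=lcc)
    if len(positives) < 4:
        raise ValueError(f"only {len(positives)} directed positives; cannot train")
    n_neg = int(round(config.negative_ratio * len(positives)))
    negatives = tr.build_negatives(
        lcc,
        positives,
        seed=config.seed,
        size=n_neg,
        exclude_reverse=config.exclude_reverse_negatives,
    )
    logger.info("training set: %d positives / %d negatives", len(positives), len(negatives))
    summary["n_positives"] = len(positives)
    summary["n_negatives"] = len(negatives)
    train_df = pd.DataFrame(
        {
            "p1": [p.effector for p in positives],
            "effector_type": [p.effector_type for p in positives],
            "p2": [p.target for p in positives],
        }
    )
    net_io.write_training_table(train_df, outdir / "training_pairs.tsv", provenance)

    # --- model ----------------------------------------------------------------
    pairs = positives + negatives
    train_pairs, test_pairs = rf.split_train_test(
        pairs, config.train_fraction, seed=config.seed
    )
    Xtr, ytr = rf.feature_matrix(train_pairs, node_table, config.angular_span)
    Xte, yte = rf.feature_matrix(test_pairs, node_table, config.angular_span)
    model, cv_acc = rf.train_rf(
        Xtr,
        ytr,
        ntrees=config.ntrees,
        mtry=config.mtry,
        folds=config.folds,
        repeats=config.repeats,
        seed=config.seed,
    )
    report = rf.evaluate(model, Xte, yte, config.threshold)
    importance = rf.feature_importance(model, Xte, yte, seed=config.seed)
    rf.save_model(model, outdir / "model.pkl")
    summary["cv_accuracy"] = cv_acc
    summary["evaluation"] = report.to_dict()
    summary["feature_importance"] = [[n, float(v)] for n, v in importance]

    # --- proteome-wide predictions -------------------------------------------
    predictions = pred.score_all_edges(
        model, lcc, node_table, config.angular_span, config.threshold
    )
    net_io.write_predictions(predictions, outdir / "predictions.tsv", provenance)
    counts = pred.threshold_counts(predictions, [0.5, 0.9])
    summary["n_prediction_records"] = len(predictions)
    summary["threshold_counts"] = {str(k): v for k, v in counts.items()}

    with open(outdir / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", outdir)
    return summary
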