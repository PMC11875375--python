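"""Shared fixtures.

The expensive artifacts — a planted popularity-similarity study at N=1000
and a fully cross-validated random forest trained on it — are session-scoped
so the classifier, predictor and acceptance tests share one computation.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import hyperptm as hp
from hyperptm.centrality import compute_centralities
from hyperptm.training import LabeledPair, build_negatives


@pytest.fixture(scope="session")
def planted_study():
    """Two-sector planted study: N=1000, m=4, gamma=2.5, T=0.3, 150 positives,
    effector sectors of width 0.3, distance weight lambda=1."""
    params = hp.PSParams(n=1000, m=4, gamma=2.5, temperature=0.3, seed=1)
    emb = hp.generate_ps_network(params)
    annot = hp.plant_effectors(emb, spread=0.3, seed=2)
    annot = hp.plant_positive_pairs(emb, annot, n_pos=150, lam=1.0, seed=3)
    cent = compute_centralities(emb.net)
    node_table = emb.coords.join(cent).rename_axis("id").reset_index()
    return {"params": params, "emb": emb, "annot": annot, "node_table": node_table}


@pytest.fixture(scope="session")
def planted_model(planted_study):
    """Full-protocol forest (500 trees, mtry 14, 5x10 under-sampled CV) on the
    planted study with balanced negatives, split 70/30."""
    emb = planted_study["emb"]
    annot = planted_study["annot"]
    node_table = planted_study["node_table"]
    pos = [LabeledPair(e, t, True, ty) for e, t, ty in annot.positive_pairs]
    neg = build_negatives(emb.net, pos, seed=4, size=len(pos))
    train_pairs, test_pairs = hp.split_train_test(pos + neg, 0.7, seed=5)
    Xtr, ytr = hp.feature_matrix(train_pairs, node_table)
    Xte, yte = hp.feature_matrix(test_pairs, node_table)
    model, cv_accuracy = hp.train_rf(Xtr, ytr, seed=6)
    report = hp.evaluate(model, Xte, yte)
    importance = hp.feature_importance(model, Xte, yte, seed=7)
    return {
        "model": model,
        "cv_accuracy": cv_accuracy,
        "report": report,
        "importance": importance,
        "Xtr": Xtr,
        "ytr": ytr,
        "Xte": Xte,
        "yte": yte,
    }


@pytest.fixture(scope="session")
def small_ps_embedding():
    """PS network (N=500, m=4, T=0.1, gamma=2.5) with its LaBNE and refined
    angle inferences, shared by embedding and acceptance tests."""
    from hyperptm.embedding import (
        assign_radial_coords,
        hypermap_refine,
        labne_angles,
        log_likelihood,
    )

    emb = hp.generate_ps_network(
        hp.PSParams(n=500, m=4, gamma=2.5, temperature=0.1, seed=7)
    )
    nodes = sorted(emb.net.nodes)
    radii = assign_radial_coords(emb.net, 2.5)
    labne = labne_angles(emb.net)
    refined = hypermap_refine(emb.net, radii, labne, 2.5, 0.1, seed=0)
    coords_labne = pd.DataFrame(
        {"r": radii.reindex(nodes), "theta": labne.reindex(nodes)}
    )
    coords_refined = coords_labne.assign(theta=refined.reindex(nodes))
    return {
        "emb": emb,
        "radii": radii,
        "labne": labne,
        "refined": refined,
        "ll_labne": log_likelihood(emb.net, coords_labne, 0.1),
        "ll_refined": log_likelihood(emb.net, coords_refined, 0.1),
        "coords_refined": coords_refined,
    }


@pytest.fixture()
def quick_rf_settings():
    """Reduced forest settings for tests exercising mechanics, not metrics."""
    return dict(ntrees=100, repeats=2)


@pytest.fixture()
def toy_node_table():
    rng = np.random.default_rng(0)
    n = 12
    ids = [f"N{i:02d}" for i in range(n)]
    return pd.DataFrame(
        {
            "id": ids,
            "r": rng.uniform(1, 10, n),
            "theta": rng.uniform(0, 2 * np.pi, n),
            "DC": rng.integers(1, 10, n).astype(float),
            "BC": rng.uniform(0, 1, n),
            "CC": rng.uniform(0, 1, n),
            "EC": rng.uniform(0.01, 1, n),
        }
    )
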