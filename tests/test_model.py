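"""Feature assembly and the under-sampled cross-validated random forest."""

import numpy as np
import pandas as pd
import pytest

import hyperptm as hp
from hyperptm.geometry import hyperbolic_distance
from hyperptm.model import (
    FEATURE_NAMES,
    ablation_study,
    assemble_features,
    evaluate,
    feature_importance,
    load_model,
    save_model,
    score_metrics,
    split_train_test,
    train_rf,
)
from hyperptm.training import LabeledPair


class TestAssembleFeatures:
    def test_order_and_values(self, toy_node_table):
        fv = assemble_features(("N01", "N02"), toy_node_table)
        assert list(fv.index) == FEATURE_NAMES
        row = toy_node_table.set_index("id")
        assert fv["r_eff"] == row.loc["N01", "r"]
        assert fv["theta_tgt"] == row.loc["N02", "theta"]

    def test_swap_exchanges_node_blocks_keeps_edge_features(self, toy_node_table):
        fwd = assemble_features(("N01", "N02"), toy_node_table)
        rev = assemble_features(("N02", "N01"), toy_node_table)
        assert fwd["hyp_dist"] == rev["hyp_dist"]
        assert fwd["r_abs_diff"] == rev["r_abs_diff"]
        for f in ("r", "theta", "DC", "BC", "CC", "EC"):
            assert fwd[f"{f}_eff"] == rev[f"{f}_tgt"]
            assert fwd[f"{f}_tgt"] == rev[f"{f}_eff"]

    def test_edge_features_match_geometry(self, toy_node_table):
        row = toy_node_table.set_index("id")
        for a, b in [("N00", "N05"), ("N03", "N11")]:
            fv = assemble_features((a, b), toy_node_table)
            expected = hyperbolic_distance(
                row.loc[a, "r"], row.loc[a, "theta"], row.loc[b, "r"], row.loc[b, "theta"]
            )
            assert fv["hyp_dist"] == pytest.approx(expected, abs=1e-12)

    def test_identical_coordinates_zero_edge_features(self, toy_node_table):
        table = toy_node_table.copy()
        table.loc[table["id"] == "N02", ["r", "theta"]] = table.loc[
            table["id"] == "N01", ["r", "theta"]
        ].to_numpy()
        fv = assemble_features(("N01", "N02"), table)
        assert fv["hyp_dist"] == 0.0
        assert fv["r_abs_diff"] == 0.0

    def test_missing_node_named_in_error(self, toy_node_table):
        with pytest.raises(KeyError, match="GHOST"):
            assemble_features(("N01", "GHOST"), toy_node_table)

    def test_matrix_agrees_with_single_assembly(self, toy_node_table):
        pairs = [LabeledPair("N01", "N02", True), LabeledPair("N07", "N03", False)]
        X, y = hp.feature_matrix(pairs, toy_node_table)
        np.testing.assert_allclose(
            X.iloc[0].to_numpy(),
            assemble_features(("N01", "N02"), toy_node_table).to_numpy(),
        )
        assert list(y) == [True, False]


class TestSplit:
    def make_pairs(self, npos=100, nneg=100):
        pos = [LabeledPair(f"P{i}", f"Q{i}", True) for i in range(npos)]
        neg = [LabeledPair(f"A{i}", f"B{i}", False) for i in range(nneg)]
        return pos + neg

    def test_stratified_arithmetic(self):
        train, test = split_train_test(self.make_pairs(), 0.7, seed=1)
        assert len(train) == 140 and len(test) == 60
        assert sum(p.label for p in train) == 70
        assert sum(p.label for p in test) == 30

    def test_deterministic_and_disjoint(self):
        pairs = self.make_pairs(20, 20)
        a_train, a_test = split_train_test(pairs, 0.7, seed=3)
        b_train, b_test = split_train_test(pairs, 0.7, seed=3)
        assert a_train == b_train and a_test == b_test
        ids = lambda ps: {(p.effector, p.target) for p in ps}
        assert ids(a_train).isdisjoint(ids(a_test))

    def test_tiny_class_rejected(self):
        pairs = [LabeledPair("A", "B", True)] + [
            LabeledPair(f"X{i}", f"Y{i}", False) for i in range(5)
        ]
        with pytest.raises(ValueError, match="fewer than 2"):
            split_train_test(pairs, 0.7, seed=0)


def random_xy(n=400, n_features=14, seed=0, signal=False):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, n_features)), columns=FEATURE_NAMES[:n_features]
    )
    if signal:
        y = X["theta_eff"].to_numpy() + 0.3 * rng.normal(size=n) > 0
    else:
        y = rng.random(n) < 0.5
    return X, y


class TestTrainRF:
    def test_mtry_cannot_exceed_feature_count(self):
        X, y = random_xy(40)
        with pytest.raises(ValueError, match="mtry"):
            train_rf(X, y, mtry=15, ntrees=10, repeats=1)

    def test_single_class_rejected(self):
        X, _ = random_xy(40)
        with pytest.raises(ValueError, match="both classes"):
            train_rf(X, np.ones(40, dtype=bool), ntrees=10, repeats=1)

    def test_undersampling_balances_every_fold(self, quick_rf_settings):
        rng = np.random.default_rng(1)
        X, _ = random_xy(300, seed=1)
        y = np.zeros(300, dtype=bool)
        y[rng.choice(300, 60, replace=False)] = True  # 1:4 imbalance
        model, _ = train_rf(X, y, seed=2, **quick_rf_settings)
        for fold in model.metadata["cv_record"]:
            assert fold["n_pos"] == fold["n_neg"]
        assert model.metadata["final_n_pos"] == model.metadata["final_n_neg"]

    def test_no_signal_accuracy_near_chance(self):
        X, y = random_xy(400, seed=3)
        _, cv_acc = train_rf(X, y, ntrees=200, repeats=3, seed=4)
        assert cv_acc == pytest.approx(0.5, abs=0.07)

    def test_deterministic_under_seed(self, quick_rf_settings):
        X, y = random_xy(120, seed=5, signal=True)
        m1, a1 = train_rf(X, y, seed=6, **quick_rf_settings)
        m2, a2 = train_rf(X, y, seed=6, **quick_rf_settings)
        assert a1 == a2
        np.testing.assert_array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_planted_signal_cv_accuracy(self, planted_model):
        # two-sector planted study (N=1000, 150 positives, balanced negatives)
        assert planted_model["cv_accuracy"] >= 0.75


class TestEvaluate:
    def test_perfect_separation(self):
        y = np.array([True] * 10 + [False] * 10)
        scores = np.array([0.9] * 10 + [0.1] * 10)
        rep = score_metrics(y, scores)
        assert rep.auc == pytest.approx(1.0)
        assert rep.accuracy == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(7)
        y = np.concatenate([np.ones(200, bool), np.zeros(200, bool)])
        rep = score_metrics(y, rng.random(400))
        assert rep.auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            score_metrics(np.ones(5, bool), np.linspace(0, 1, 5))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_auc_matches_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        y = rng.random(n) < 0.4
        if y.all() or not y.any():
            y[:2] = [True, False]
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        rep = score_metrics(y, scores)
        pos, neg = scores[y], scores[~y]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert rep.auc == pytest.approx(oracle, abs=1e-9)

    def test_confusion_consistent_with_accuracy(self, planted_model):
        rep = planted_model["report"]
        total = rep.tp + rep.fp + rep.tn + rep.fn
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / total)


class TestImportanceAndAblation:
    def test_constant_feature_unimportant(self, quick_rf_settings):
        X, y = random_xy(200, seed=8, signal=True)
        X["DC_eff"] = 1.0
        model, _ = train_rf(X, y, seed=9, **quick_rf_settings)
        imp = dict(feature_importance(model, X, y, n_repeats=10, seed=10))
        assert imp["DC_eff"] <= 0.01

    def test_theta_features_lead_when_only_angle_is_informative(self):
        # labels depend on the two theta columns only; every other feature is noise
        rng = np.random.default_rng(11)
        n = 500
        X = pd.DataFrame(rng.normal(size=(n, 14)), columns=FEATURE_NAMES)
        X["theta_eff"] = rng.uniform(0, 2 * np.pi, n)
        X["theta_tgt"] = rng.uniform(0, 2 * np.pi, n)
        y = (np.abs(X["theta_eff"] - 1.8) < 0.8) & (np.abs(X["theta_tgt"] - 3.0) < 1.5)
        y = y.to_numpy()
        y[rng.random(n) < 0.05] ^= True  # label noise
        model, _ = train_rf(X, y, ntrees=200, repeats=2, seed=12)
        ranked = [name for name, _ in feature_importance(model, X, y, seed=13)]
        assert set(ranked[:3]) >= {"theta_eff", "theta_tgt"}

    def test_single_model_ablation_is_full_auc(self, quick_rf_settings):
        X, y = random_xy(200, seed=14, signal=True)
        tr, te = slice(0, 140), slice(140, 200)
        out = ablation_study(
            X[tr], y[tr], X[te], y[te], removal_order=list(X.columns),
            n_models=1, seed=15, **quick_rf_settings,
        )
        assert len(out) == 1
        assert out[0][0] == tuple(X.columns)
        assert 0.0 <= out[0][1] <= 1.0

    def test_masking_noise_feature_barely_moves_auc(self, quick_rf_settings):
        X, y = random_xy(300, seed=16, signal=True)
        X["BC_tgt"] = np.random.default_rng(17).normal(size=300)  # pure noise
        tr, te = slice(0, 210), slice(210, 300)
        out = ablation_study(
            X[tr], y[tr], X[te], y[te], removal_order=["BC_tgt"],
            n_models=2, step=1, seed=18, **quick_rf_settings,
        )
        assert abs(out[0][1] - out[1][1]) < 0.05


def test_model_save_load_round_trip(tmp_path, quick_rf_settings):
    X, y = random_xy(100, seed=19, signal=True)
    model, _ = train_rf(X, y, seed=20, **quick_rf_settings)
    path = tmp_path / "model.pkl"
    save_model(model, path)
    back = load_model(path)
    np.testing.assert_array_equal(back.predict_proba(X), model.predict_proba(X))
    assert back.feature_names == model.feature_names
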