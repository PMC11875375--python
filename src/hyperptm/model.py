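"""Random-forest classification of directed phospho-interaction candidates.

Each directed candidate pair is described by 14 features: the hyperbolic
coordinates (r, theta) and four centralities (DC, BC, CC, EC) of the effector
and of the target, plus two edge-level quantities — the hyperbolic distance
between the pair and the absolute radial difference.

Training follows a class-imbalance-aware protocol: a stratified 70/30
train/test split, then five-fold cross-validation repeated ten times on the
training partition, down-sampling the majority class to the minority size
inside every fold's training portion.  The forest uses 500 CART/Gini trees
with all 14 features tried at every split (mtry = 14), and scores a pair by
the fraction of trees voting positive.  All randomness flows from one seed
through documented substreams (split -> folds -> under-sampling -> trees ->
permutations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .geometry import TWO_PI, hyperbolic_distance, radial_difference
from .training import LabeledPair

__all__ = [
    "FEATURE_NAMES",
    "TrainedModel",
    "EvaluationReport",
    "assemble_features",
    "feature_matrix",
    "split_train_test",
    "train_rf",
    "evaluate",
    "score_metrics",
    "feature_importance",
    "ablation_study",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES = [
    "r_eff",
    "theta_eff",
    "DC_eff",
    "BC_eff",
    "CC_eff",
    "EC_eff",
    "r_tgt",
    "theta_tgt",
    "DC_tgt",
    "BC_tgt",
    "CC_tgt",
    "EC_tgt",
    "hyp_dist",
    "r_abs_diff",
]

_NODE_FEATS = ["r", "theta", "DC", "BC", "CC", "EC"]


def _indexed(node_table: pd.DataFrame) -> pd.DataFrame:
    return node_table.set_index("id") if "id" in node_table.columns else node_table


def assemble_features(
    pair: tuple[str, str] | LabeledPair, node_table: pd.DataFrame, w: float = TWO_PI
) -> pd.Series:
    """The 14-entry feature vector for one directed (effector, target) pair."""
    if isinstance(pair, LabeledPair):
        eff, tgt = pair.effector, pair.target
    else:
        eff, tgt = pair
    table = _indexed(node_table)
    for node in (eff, tgt):
        if node not in table.index:
            raise KeyError(f"node {node!r} missing from the node table")
    e = table.loc[eff, _NODE_FEATS]
    t = table.loc[tgt, _NODE_FEATS]
    d = hyperbolic_distance(e["r"], e["theta"], t["r"], t["theta"], w)
    values = list(e) + list(t) + [d, radial_difference(e["r"], t["r"])]
    return pd.Series(values, index=FEATURE_NAMES, dtype=float)


def feature_matrix(
    pairs, node_table: pd.DataFrame, w: float = TWO_PI
) -> tuple[pd.DataFrame, np.ndarray]:
    """Vectorized feature assembly for a list of labeled pairs.

    Returns the feature DataFrame (columns in canonical order) and the
    boolean label vector.
    """
    table = _indexed(node_table)
    effs = [p.effector for p in pairs]
    tgts = [p.target for p in pairs]
    missing = (set(effs) | set(tgts)) - set(table.index)
    if missing:
        raise KeyError(f"nodes missing from the node table: {sorted(missing)[:5]}")
    e = table.loc[effs, _NODE_FEATS].to_numpy(dtype=float)
    t = table.loc[tgts, _NODE_FEATS].to_numpy(dtype=float)
    d = hyperbolic_distance(e[:, 0], e[:, 1], t[:, 0], t[:, 1], w)
    rdiff = np.abs(e[:, 0] - t[:, 0])
    X = pd.DataFrame(
        np.column_stack([e, t, d, rdiff]), columns=FEATURE_NAMES
    )
    y = np.array([p.label for p in pairs], dtype=bool)
    return X, y


def split_train_test(pairs, train_fraction: float = 0.7, seed: int = 0):
    """Stratified split of labeled pairs into train and test lists."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    labels = [p.label for p in pairs]
    for cls in (True, False):
        if labels.count(cls) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members; cannot stratify")
    train, test = train_test_split(
        list(pairs),
        train_size=train_fraction,
        stratify=labels,
        random_state=seed % (2**32),
        shuffle=True,
    )
    return train, test


@dataclass
class TrainedModel:
    """A fitted forest plus the metadata needed to reproduce it."""

    estimator: RandomForestClassifier
    feature_names: list
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, X) -> np.ndarray:
        """Score = fraction of trees voting for the positive class."""
        arr = (
            X[self.feature_names].to_numpy(dtype=float)
            if isinstance(X, pd.DataFrame)
            else np.asarray(X, dtype=float)
        )
        votes = np.zeros(len(arr))
        for tree in self.estimator.estimators_:
            votes += tree.predict(arr)
        return votes / len(self.estimator.estimators_)


def _undersample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices keeping all minority samples and an equal-size majority draw."""
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    kept = rng.choice(majority, size=len(minority), replace=False)
    return np.sort(np.concatenate([minority, kept]))


def train_rf(
    X: pd.DataFrame,
    y: np.ndarray,
    ntrees: int = 500,
    mtry: int = 14,
    folds: int = 5,
    repeats: int = 10,
    undersample: bool = True,
    seed: int = 0,
) -> tuple[TrainedModel, float]:
    """Under-sampled repeated cross-validation, then a final refit.

    ``cv_accuracy`` is the mean held-out accuracy (threshold 0.5) over the
    ``folds x repeats`` validation folds; the returned model is refit on the
    full (under-sampled) training data.
    """
    y = np.asarray(y, dtype=bool)
    n_features = X.shape[1]
    if mtry > n_features:
        raise ValueError(f"mtry={mtry} exceeds the {n_features} available features")
    if y.all() or not y.any():
        raise ValueError("both classes must be present for training")
    ss = np.random.SeedSequence(seed)
    fold_seeds, under_seed, tree_seed = ss.spawn(3)
    under_rng = np.random.default_rng(under_seed)
    fold_rngs = fold_seeds.spawn(repeats)
    tree_states = tree_seed.generate_state(repeats * folds + 1) % (2**31)

    Xa = X.to_numpy(dtype=float)
    accuracies = []
    record = []
    k = 0
    for rep in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds,
            shuffle=True,
            random_state=int(fold_rngs[rep].generate_state(1)[0] % (2**31)),
        )
        for fold, (tr, va) in enumerate(skf.split(Xa, y)):
            if undersample:
                keep = _undersample(y[tr], under_rng)
                tr = tr[keep]
            forest = RandomForestClassifier(
                n_estimators=ntrees,
                criterion="gini",
                max_features=mtry,
                bootstrap=True,
                random_state=int(tree_states[k]),
                n_jobs=1,
            )
            forest.fit(Xa[tr], y[tr])
            acc = float(np.mean(forest.predict(Xa[va]) == y[va]))
            accuracies.append(acc)
            record.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "n_pos": int(y[tr].sum()),
                    "n_neg": int((~y[tr]).sum()),
                    "accuracy": acc,
                }
            )
            k += 1
    cv_accuracy = float(np.mean(accuracies)) if accuracies else float("nan")

    final_idx = _undersample(y, under_rng) if undersample else np.arange(len(y))
    final = RandomForestClassifier(
        n_estimators=ntrees,
        criterion="gini",
        max_features=mtry,
        bootstrap=True,
        random_state=int(tree_states[-1]),
        n_jobs=1,
    )
    final.fit(Xa[final_idx], y[final_idx])
    model = TrainedModel(
        estimator=final,
        feature_names=list(X.columns),
        metadata={
            "seed": seed,
            "folds": folds,
            "repeats": repeats,
            "ntrees": ntrees,
            "mtry": mtry,
            "undersample": undersample,
            "cv_record": record,
            "final_n_pos": int(y[final_idx].sum()),
            "final_n_neg": int((~y[final_idx]).sum()),
        },
    )
    return model, cv_accuracy


@dataclass
class EvaluationReport:
    """Threshold metrics plus the full ROC and precision-recall curves."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    roc: pd.DataFrame
    auc: float
    pr: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def evaluate(
    model: TrainedModel, X_test: pd.DataFrame, y_test: np.ndarray, threshold: float = 0.5
) -> EvaluationReport:
    """Confusion-matrix metrics at ``threshold`` plus ROC/AUC and PR curves."""
    return score_metrics(y_test, model.predict_proba(X_test), threshold)


def score_metrics(
    y_test: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> EvaluationReport:
    """Metrics from labels and scores directly.

    AUC is the trapezoid-rule area under the threshold-swept ROC, which
    coincides with the probability that a random positive outscores a random
    negative (ties counting one half).
    """
    y_test = np.asarray(y_test, dtype=bool)
    if y_test.all() or not y_test.any():
        raise ValueError("test set holds a single class; ROC is undefined")
    scores = np.asarray(scores, dtype=float)
    pred = scores >= threshold
    tp = int(np.sum(pred & y_test))
    fp = int(np.sum(pred & ~y_test))
    tn = int(np.sum(~pred & ~y_test))
    fn = int(np.sum(~pred & y_test))
    fpr, tpr, thr = roc_curve(y_test, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    precision, recall, _ = precision_recall_curve(y_test, scores)
    return EvaluationReport(
        threshold=threshold,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=(tp + tn) / len(y_test),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        auc=auc,
        pr=pd.DataFrame({"precision": precision, "recall": recall}),
    )


def feature_importance(
    model: TrainedModel,
    X: pd.DataFrame,
    y: np.ndarray,
    n_repeats: int = 20,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Permutation importance: mean accuracy drop over seeded shuffles.

    Sorted descending; ties resolved by canonical feature order.
    """
    y = np.asarray(y, dtype=bool)
    arr = X[model.feature_names].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    base = float(np.mean((model.predict_proba(arr) >= 0.5) == y))
    drops = []
    for j, name in enumerate(model.feature_names):
        accs = []
        for _ in range(n_repeats):
            perm = arr.copy()
            perm[:, j] = perm[rng.permutation(len(perm)), j]
            accs.append(float(np.mean((model.predict_proba(perm) >= 0.5) == y)))
        drops.append((name, base - float(np.mean(accs))))
    order = sorted(
        range(len(drops)), key=lambda i: (-drops[i][1], i)
    )  # stable: ties keep feature order
    return [drops[i] for i in order]


_MODEL_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model (pickle, with a format-version stamp)."""
    import pickle

    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "feature_names": model.feature_names,
        "metadata": model.metadata,
        "estimator": model.estimator,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> TrainedModel:
    import pickle

    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model file version in {path}")
    return TrainedModel(
        estimator=payload["estimator"],
        feature_names=payload["feature_names"],
        metadata=payload["metadata"],
    )


def ablation_study(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    removal_order: list[str],
    n_models: int = 5,
    step: int = 2,
    seed: int = 0,
    **rf_kwargs,
) -> list[tuple[tuple, float]]:
    """Nested-subset masking study.

    Model ``i`` drops the first ``i * step`` features of ``removal_order``
    (model 0 keeps everything), is trained with the full cross-validation
    protocol, and is scored by test AUC.  Stops early with a warning if a
    subset would be empty.
    """
    unknown = set(removal_order) - set(X_train.columns)
    if unknown:
        raise ValueError(f"removal_order names unknown features: {sorted(unknown)}")
    results = []
    for i in range(n_models):
        masked = set(removal_order[: i * step])
        subset = tuple(c for c in X_train.columns if c not in masked)
        if not subset:
            logger.warning("ablation stopped early: all features masked at model %d", i)
            break
        kwargs = dict(rf_kwargs)
        kwargs.setdefault("mtry", len(subset))
        kwargs["mtry"] = min(kwargs["mtry"], len(subset))
        model, _ = train_rf(
            X_train[list(subset)], y_train, seed=seed + i, **kwargs
        )
        report = evaluate(model, X_test[list(subset)], y_test)
        results.append((subset, report.auc))
    return results
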