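"""Afferent/efferent classification: splits, training, tuning, evaluation.

Class convention: 0 = efferent, 1 = afferent. Two split schemes are
supported. Model 1 pools every experiment's windows, splits 60/40 into a
training pool and a test set (stratified by class), then splits the pool
85/15 into inner training and validation. Model 2 holds out one whole
experiment as the test set and splits the remainder 85/15. All splits use
floor rounding per class with the remainder going to the test/validation
side, and are reproducible under a seed.

Four classifier families are provided: SVM with Gaussian (RBF) kernel — the
primary model — k-nearest neighbours with a large ("coarse") k, AdaBoost
over depth-1 trees, and a one-hidden-layer 10-unit neural network. Features
are z-scored using training-partition statistics only. The
misclassification penalty per class (class weight) is tunable on the
validation set: the selected ratio minimises the gap between the two
per-class recalls, which is how an imbalanced decision boundary is
rebalanced (a ratio of 1.5:1 afferent:efferent is the canonical example).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES

ALGORITHMS = ("svm_gaussian", "knn_coarse", "adaboost_tree", "nn_1hidden_10units")

CLASS_NAMES = {0: "efferent", 1: "afferent"}
LABEL_TO_CLASS = {"efferent": 0, "afferent": 1}


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def _stratified_take(df: pd.DataFrame, fraction: float, rng: np.random.Generator):
    """Per-class floor-rounded draw; returns (taken, remainder)."""
    take_idx = []
    for _, grp in df.groupby("label", sort=True):
        idx = grp.index.to_numpy()
        idx = idx[rng.permutation(idx.size)]
        take_idx.append(idx[: int(np.floor(fraction * idx.size))])
    take = np.concatenate(take_idx) if take_idx else np.array([], dtype=int)
    taken = df.loc[np.sort(take)]
    remainder = df.drop(index=take)
    return taken, remainder


def split_model1(
    dataset: pd.DataFrame, seed: int = 0, train_frac: float = 0.60, inner_train_frac: float = 0.85
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pooled 60/40 split, then 85/15 within the training pool.

    Returns (train, validation, test); partitions are disjoint, exhaustive
    and stratified by class.
    """
    if len(dataset) < 10:
        raise ValueError("dataset too small to split (need >= 10 rows)")
    if not dataset.index.is_unique:
        dataset = dataset.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    pool, test = _stratified_take(dataset, train_frac, rng)
    train, validation = _stratified_take(pool, inner_train_frac, rng)
    return train, validation, test


def split_model2(
    dataset: pd.DataFrame, held_out_experiment, seed: int = 0, inner_train_frac: float = 0.85
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Leave-one-experiment-out: the held-out experiment is the test set."""
    if "experiment_id" not in dataset.columns:
        raise ValueError("dataset must carry an 'experiment_id' column")
    ids = set(dataset["experiment_id"].unique())
    if held_out_experiment not in ids:
        raise ValueError(f"unknown experiment id {held_out_experiment!r}")
    if len(ids) < 2:
        raise ValueError("need at least 2 experiments for a model-2 split")
    if not dataset.index.is_unique:
        dataset = dataset.reset_index(drop=True)
    test = dataset[dataset["experiment_id"] == held_out_experiment]
    rest = dataset[dataset["experiment_id"] != held_out_experiment]
    rng = np.random.default_rng(seed)
    train, validation = _stratified_take(rest, inner_train_frac, rng)
    return train, validation, test


def _xy(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = df["label"].to_numpy()
    if y.dtype == object:
        y = np.array([LABEL_TO_CLASS.get(v, v) for v in y])
    return X, y.astype(int)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    algorithm: str
    scaler: StandardScaler
    estimator: object
    class_weights: dict[int, float]
    metadata: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(FEATURE_NAMES)].to_numpy(dtype=float)
        return self.estimator.predict(self.scaler.transform(X))

    def decision_scores(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Continuous score increasing with the afferent (class-1) evidence."""
        if isinstance(X, pd.DataFrame):
            X = X[list(FEATURE_NAMES)].to_numpy(dtype=float)
        Xs = self.scaler.transform(X)
        est = self.estimator
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(Xs), dtype=float)
        return np.asarray(est.predict_proba(Xs)[:, 1], dtype=float)


def _median_heuristic_gamma(X: np.ndarray, rng: np.random.Generator, max_rows: int = 400) -> float:
    """RBF width from the median pairwise squared distance of a subsample."""
    sub = X[rng.permutation(X.shape[0])[:max_rows]]
    d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    return 1.0 / med if med > 0 else 1.0 / X.shape[1]


def train_classifier(
    train: pd.DataFrame,
    algorithm: str = "svm_gaussian",
    hyperparams: dict | None = None,
    class_weights: dict | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit one classifier family on a labelled feature table.

    ``class_weights`` maps class (0/1 or 'efferent'/'afferent') to its
    misclassification penalty; it is applied to weight-aware learners and
    always echoed in the model metadata.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unsupported algorithm {algorithm!r}; choose from {ALGORITHMS}")
    hyperparams = dict(hyperparams or {})
    X, y = _xy(train)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data contains a single class")

    cw = {0: 1.0, 1: 1.0}
    for k, v in (class_weights or {}).items():
        cw[LABEL_TO_CLASS.get(k, k)] = float(v)

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    rng = np.random.default_rng(seed)

    if algorithm == "svm_gaussian":
        gamma = hyperparams.pop("gamma", None) or _median_heuristic_gamma(Xs, rng)
        est = SVC(
            kernel="rbf",
            C=hyperparams.pop("C", 30.0),
            gamma=gamma,
            class_weight=cw,
            random_state=seed,
            **hyperparams,
        )
        est.fit(Xs, y)
    elif algorithm == "knn_coarse":
        k = min(hyperparams.pop("n_neighbors", 100), len(y))
        est = KNeighborsClassifier(n_neighbors=k, **hyperparams)
        est.fit(Xs, y)  # distance voting is weight-agnostic; cw echoed only
    elif algorithm == "adaboost_tree":
        est = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=hyperparams.pop("n_estimators", 30),
            random_state=seed,
            **hyperparams,
        )
        sw = np.array([cw[c] for c in y], dtype=float)
        est.fit(Xs, y, sample_weight=sw / sw.mean())
    else:  # nn_1hidden_10units
        est = MLPClassifier(
            hidden_layer_sizes=(10,),
            activation="logistic",
            early_stopping=True,
            max_iter=hyperparams.pop("max_iter", 300),
            random_state=seed,
            **hyperparams,
        )
        est.fit(Xs, y)

    return TrainedModel(
        algorithm=algorithm,
        scaler=scaler,
        estimator=est,
        class_weights=cw,
        metadata={"seed": seed, "n_train": len(y), "class_weights": dict(cw)},
    )


def tune_class_weights(
    algorithm: str,
    train: pd.DataFrame,
    validation: pd.DataFrame,
    grid: tuple[float, ...] = (1.0, 1.25, 1.5, 2.0),
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Pick the afferent:efferent penalty ratio balancing per-class recall.

    Each grid ratio r trains with weights {efferent: 1, afferent: r}; the
    ratio minimising |recall(efferent) - recall(afferent)| on the validation
    set wins, ties going to the smaller ratio. Returns (best_ratio, table of
    per-ratio recalls).
    """
    if len(validation) == 0 or len(grid) == 0:
        raise ValueError("validation set and grid must be nonempty")
    Xv, yv = _xy(validation)
    rows = []
    for r in sorted(grid):
        model = train_classifier(train, algorithm, class_weights={0: 1.0, 1: r}, seed=seed)
        pred = model.estimator.predict(model.scaler.transform(Xv))
        rec0 = float(np.mean(pred[yv == 0] == 0)) if (yv == 0).any() else np.nan
        rec1 = float(np.mean(pred[yv == 1] == 1)) if (yv == 1).any() else np.nan
        rows.append({"ratio": r, "recall_efferent": rec0, "recall_afferent": rec1,
                     "gap": abs(rec0 - rec1)})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["gap"].idxmin(), "ratio"])  # idxmin → first/smallest on ties
    return best, table


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Confusion matrix (rows = true class, cols = predicted), per-class
    precision/recall/F1, accuracy, ROC points and trapezoidal AUC."""

    confusion: np.ndarray
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    accuracy: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float | None

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "precision": {CLASS_NAMES[k]: v for k, v in self.precision.items()},
            "recall": {CLASS_NAMES[k]: v for k, v in self.recall.items()},
            "f1": {CLASS_NAMES[k]: v for k, v in self.f1.items()},
            "accuracy": self.accuracy,
            "auc": self.auc,
        }


def _roc_points(y: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(-scores, kind="stable")
    y = y[order]
    tp = np.concatenate([[0], np.cumsum(y == 1)])
    fp = np.concatenate([[0], np.cumsum(y == 0)])
    tpr = tp / max((y == 1).sum(), 1)
    fpr = fp / max((y == 0).sum(), 1)
    return fpr, tpr


def evaluate(model: TrainedModel, test: pd.DataFrame) -> EvalReport:
    """Score a trained model on a labelled test table."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    X, y = _xy(test)
    pred = model.predict(test)
    cm = _sk_confusion(y, pred, labels=[0, 1])
    precision, recall, f1 = {}, {}, {}
    for c in (0, 1):
        tp = cm[c, c]
        p = tp / cm[:, c].sum() if cm[:, c].sum() else 0.0
        r = tp / cm[c, :].sum() if cm[c, :].sum() else 0.0
        precision[c], recall[c] = float(p), float(r)
        f1[c] = float(2 * p * r / (p + r)) if (p + r) else 0.0
    accuracy = float(np.trace(cm) / cm.sum())

    if np.unique(y).size < 2:
        warnings.warn("test set contains a single class; AUC undefined")
        return EvalReport(cm, precision, recall, f1, accuracy,
                          np.array([0.0, 1.0]), np.array([0.0, 1.0]), None)
    scores = model.decision_scores(test)
    fpr, tpr = _roc_points(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return EvalReport(cm, precision, recall, f1, accuracy, fpr, tpr, auc)


def predict_afferent_fraction(model: TrainedModel, features: pd.DataFrame) -> float | None:
    """Fraction of windows predicted afferent (class 1); None when empty."""
    if len(features) == 0:
        warnings.warn("empty epoch: afferent fraction undefined")
        return None
    pred = model.predict(features)
    return float(np.mean(pred == 1))
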