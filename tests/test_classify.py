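"""Split accounting, training, weight tuning and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.preprocessing import StandardScaler

from dircuff.classify import (
    ALGORITHMS,
    TrainedModel,
    evaluate,
    predict_afferent_fraction,
    split_model1,
    split_model2,
    train_classifier,
    tune_class_weights,
)
from dircuff.features import FEATURE_NAMES


def _dataset(n_per_class: int, n_experiments: int = 1, seed: int = 0) -> pd.DataFrame:
    """Two separable Gaussian blobs in 20-feature space."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, centre in ((0, -2.0), (1, 2.0)):
        X = rng.normal(loc=centre, scale=1.0, size=(n_per_class, len(FEATURE_NAMES)))
        df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
        df["label"] = label
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out["experiment_id"] = np.arange(len(out)) % n_experiments
    return out


class TestSplitModel1:
    def test_exact_floor_rounded_sizes(self):
        df = _dataset(1904)  # 3808 rows; the published corpus scaled by 1/100
        train, val, test = split_model1(df, seed=0)
        assert len(train) + len(val) == 2284  # 60% pool
        assert len(test) == 1524
        assert len(train) == 1940 and len(val) == 344  # 85/15 of the pool

    def test_partitions_disjoint_and_exhaustive_and_stratified(self):
        df = _dataset(500)
        train, val, test = split_model1(df, seed=3)
        idx = np.concatenate([train.index, val.index, test.index])
        assert len(np.unique(idx)) == len(df) == len(idx)
        for part in (train, val, test):
            counts = part["label"].value_counts()
            assert abs(counts[0] - counts[1]) <= 1

    def test_reproducible_under_seed(self):
        df = _dataset(100)
        a = split_model1(df, seed=9)
        b = split_model1(df, seed=9)
        for x, y in zip(a, b):
            assert x.index.equals(y.index)

    def test_tiny_dataset_rejected(self):
        with pytest.raises(ValueError):
            split_model1(_dataset(4).head(8))


class TestSplitModel2:
    def test_held_out_experiment_is_the_test_set(self):
        df = _dataset(300, n_experiments=6)
        train, val, test = split_model2(df, held_out_experiment=3, seed=0)
        assert set(test["experiment_id"]) == {3}
        assert 3 not in set(train["experiment_id"]) | set(val["experiment_id"])

    def test_remaining_rows_split_85_15(self):
        df = _dataset(600, n_experiments=6)
        train, val, test = split_model2(df, held_out_experiment=0, seed=1)
        rest = len(df) - len(test)
        assert len(train) == pytest.approx(0.85 * rest, abs=2)
        assert len(train) + len(val) == rest

    def test_unknown_experiment_errors(self):
        with pytest.raises(ValueError):
            split_model2(_dataset(50, n_experiments=2), held_out_experiment=99)


class TestTraining:
    def test_svm_separates_gaussian_blobs(self):
        df = _dataset(100)
        model = train_classifier(df, "svm_gaussian", seed=0)
        assert np.mean(model.predict(df) == df["label"]) > 0.99

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_all_families_fit_and_score(self, algorithm):
        df = _dataset(100)
        model = train_classifier(df, algorithm, seed=0)
        assert np.mean(model.predict(df) == df["label"]) > 0.9
        assert model.decision_scores(df).shape == (len(df),)

    def test_single_class_rejected(self):
        df = _dataset(50)
        with pytest.raises(ValueError, match="single class"):
            train_classifier(df[df["label"] == 0], "svm_gaussian")

    def test_unsupported_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            train_classifier(_dataset(20), "random_forest")

    def test_class_weights_echoed_in_metadata(self):
        model = train_classifier(
            _dataset(50), "svm_gaussian", class_weights={"afferent": 1.5, "efferent": 1.0}
        )
        assert model.class_weights == {0: 1.0, 1: 1.5}
        assert model.metadata["class_weights"] == {0: 1.0, 1: 1.5}


class TestWeightTuning:
    def test_balanced_problem_tie_breaks_to_smallest_ratio(self):
        df = _dataset(200, seed=5)
        train, val, _ = split_model1(df, seed=5)
        best, table = tune_class_weights("svm_gaussian", train, val, grid=(1.0, 1.5, 2.0))
        assert best == 1.0
        assert set(table["ratio"]) == {1.0, 1.5, 2.0}

    def test_best_ratio_matches_grid_argmin(self):
        """The returned ratio is the exhaustive argmin of the recall gap."""
        rng = np.random.default_rng(0)
        # heavily overlapping classes (signal in 2 of 20 features) with a
        # 3:1 imbalance biasing recall toward the majority class 0
        rows = []
        for label, centre, n in ((0, -0.3, 1500), (1, 0.3, 500)):
            X = rng.normal(0.0, 1.0, size=(n, len(FEATURE_NAMES)))
            X[:, 0] += centre
            X[:, 1] += centre
            df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
            df["label"] = label
            rows.append(df)
        df = pd.concat(rows, ignore_index=True)
        train, val, _ = split_model1(df, seed=1)
        best, table = tune_class_weights("svm_gaussian", train, val, grid=(1.0, 1.5, 2.0, 3.0))
        gaps = table.set_index("ratio")["gap"]
        assert best == gaps.index[np.argmin(gaps.to_numpy())]
        assert best > 1.0  # penalising the minority class rebalances recall


class _FixedPredictor:
    """Deterministic stub estimator with known predictions and scores."""

    def __init__(self, preds, scores):
        self.preds = np.asarray(preds)
        self.scores = np.asarray(scores)

    def predict(self, X):
        return self.preds[: len(X)]

    def decision_function(self, X):
        return self.scores[: len(X)]


def _stub_model(preds, scores, n_features=len(FEATURE_NAMES)):
    scaler = StandardScaler()
    scaler.fit(np.random.default_rng(0).normal(size=(10, n_features)))
    return TrainedModel("svm_gaussian", scaler, _FixedPredictor(preds, scores), {0: 1.0, 1: 1.0})


def _test_frame(labels):
    df = pd.DataFrame(
        np.zeros((len(labels), len(FEATURE_NAMES))), columns=list(FEATURE_NAMES)
    )
    df["label"] = labels
    return df


class TestEvaluate:
    def test_perfect_predictions(self):
        y = [0] * 50 + [1] * 50
        model = _stub_model(y, np.array(y, dtype=float))
        rep = evaluate(model, _test_frame(y))
        assert rep.accuracy == 1.0
        assert rep.f1 == {0: 1.0, 1: 1.0}
        assert rep.auc == 1.0

    def test_always_class0_predictor(self):
        y = [0] * 50 + [1] * 50
        model = _stub_model([0] * 100, np.zeros(100))
        rep = evaluate(model, _test_frame(y))
        assert rep.accuracy == 0.5
        assert rep.recall[1] == 0.0

    def test_hand_computed_confusion_metrics(self):
        # class-1 view: TP=8, FP=2, FN=1, TN=9
        y = [1] * 9 + [0] * 11
        preds = [1] * 8 + [0] * 1 + [1] * 2 + [0] * 9
        model = _stub_model(preds, np.array(preds, dtype=float))
        rep = evaluate(model, _test_frame(y))
        assert rep.precision[1] == pytest.approx(0.800, abs=1e-3)
        assert rep.recall[1] == pytest.approx(0.889, abs=1e-3)
        assert rep.f1[1] == pytest.approx(0.842, abs=1e-3)

    def test_metrics_self_consistent_with_confusion(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        preds = rng.integers(0, 2, 200)
        model = _stub_model(preds, rng.normal(size=200))
        rep = evaluate(model, _test_frame(y))
        cm = rep.confusion
        assert cm.sum() == 200
        assert rep.accuracy == pytest.approx(np.trace(cm) / cm.sum())
        for c in (0, 1):
            assert rep.recall[c] == pytest.approx(cm[c, c] / cm[c].sum())
            assert rep.precision[c] == pytest.approx(cm[c, c] / cm[:, c].sum())
            p, r = rep.precision[c], rep.recall[c]
            if p + r:
                assert rep.f1[c] == pytest.approx(2 * p * r / (p + r))

    def test_single_class_test_flags_null_auc(self):
        model = _stub_model([0] * 20, np.zeros(20))
        with pytest.warns(UserWarning, match="single class"):
            rep = evaluate(model, _test_frame([0] * 20))
        assert rep.auc is None


class TestAfferentFraction:
    def test_always_afferent_model_gives_one(self):
        model = _stub_model([1] * 30, np.ones(30))
        assert predict_afferent_fraction(model, _test_frame([1] * 30)) == 1.0

    def test_empty_epoch_gives_none_with_warning(self):
        model = _stub_model([1], np.ones(1))
        with pytest.warns(UserWarning, match="empty"):
            assert predict_afferent_fraction(model, _test_frame([])) is None
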