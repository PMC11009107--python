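"""Classifier: dataset assembly contracts, metrics, threshold curve."""

import numpy as np
import pandas as pd
import pytest

from conftest import toy_feature_frame
from cupore.classify import (
    ALGORITHMS,
    FEATURE_COLUMNS,
    SplitSpec,
    TrainedModel,
    assemble_datasets,
    evaluate_model,
    feature_importance,
    load_model,
    predict,
    save_model,
    threshold_curve,
    train_model,
)


def labeled_toy(classes, n_per_class, n_experiments=2, sd=0.004, seed=0):
    """Well-separated labeled feature table (one blockade mode per class)."""
    rng = np.random.default_rng(seed)
    frames = []
    for i, (cls, mean) in enumerate(classes.items()):
        df = toy_feature_frame(rng.normal(mean, sd, n_per_class))
        df["label"] = cls
        df["experiment_id"] = [
            f"{cls}-e{j % n_experiments}" for j in range(n_per_class)
        ]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


class _StubEstimator:
    """Fixed-probability estimator for metric unit tests."""

    def __init__(self, classes, proba):
        self.classes_ = np.asarray(classes)
        self._proba = np.asarray(proba, dtype=float)

    def predict_proba(self, X):
        return self._proba[: len(X)]


def stub_model(classes, proba):
    return TrainedModel(algorithm="rf", estimator=_StubEstimator(classes, proba),
                        classes=list(classes))


class TestAssembleDatasets:
    def test_small_class_upsampled_to_target(self):
        data = labeled_toy({"A": 0.1, "B": 0.3}, 500)
        train, test, val = assemble_datasets(data, SplitSpec(seed=0))
        counts = train["label"].value_counts()
        assert (counts == 1000).all()

    def test_large_class_downsampled_without_replacement(self):
        data = labeled_toy({"A": 0.1, "B": 0.3}, 5000)
        train, _, _ = assemble_datasets(data, SplitSpec(seed=0))
        a = train[train["label"] == "A"]
        assert len(a) == 1000
        # downsampling keeps unique rows (blockades are almost surely distinct)
        assert a["blockade"].duplicated().sum() == 0

    def test_validation_is_whole_experiment_and_sets_disjoint(self):
        data = labeled_toy({"A": 0.1, "B": 0.3}, 300, n_experiments=3)
        spec = SplitSpec(validation_experiments={"A": "A-e0", "B": "B-e1"}, seed=1,
                         per_class_target=100)
        train, test, val = assemble_datasets(data, spec)
        assert set(val[val.label == "A"]["experiment_id"]) == {"A-e0"}
        assert set(val[val.label == "B"]["experiment_id"]) == {"B-e1"}
        assert not (set(train["experiment_id"]) & set(val["experiment_id"]))
        assert not (set(test["experiment_id"]) & set(val["experiment_id"]))
        # train/test disjoint at the row level (unique blockades as row ids)
        assert not (set(train["blockade"]) & set(test["blockade"]))

    def test_single_experiment_class_rejected(self):
        data = labeled_toy({"A": 0.1, "B": 0.3}, 100, n_experiments=1)
        with pytest.raises(ValueError, match="single experiment"):
            assemble_datasets(data, SplitSpec(seed=0))


class TestTrainModel:
    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_separable_classes_reach_perfect_cv(self, algo):
        # truly 1-D problem: the blockade separates the classes, the
        # density features carry no information
        data = labeled_toy({"A": 0.10, "B": 0.30}, 60, sd=0.002)
        from cupore.signals import FEATURE_NAMES

        data[FEATURE_NAMES] = 0.0
        model = train_model(data, algorithm=algo, cv_folds=5, seed=0)
        assert np.mean(model.cv_scores) == 1.0

    def test_shuffled_labels_score_at_chance(self):
        rng = np.random.default_rng(0)
        data = labeled_toy({"A": 0.1, "B": 0.2, "C": 0.3}, 60, sd=0.002)
        data["label"] = rng.permutation(data["label"].to_numpy())
        model = train_model(data, algorithm="rf", cv_folds=5, seed=0)
        assert abs(np.mean(model.cv_scores) - 1 / 3) < 0.2

    def test_unknown_algorithm_rejected(self):
        data = labeled_toy({"A": 0.1, "B": 0.3}, 30)
        with pytest.raises(ValueError, match="unknown algorithm"):
            train_model(data, algorithm="svm", cv_folds=3)

    def test_training_deterministic_under_seed(self):
        data = labeled_toy({"A": 0.1, "B": 0.3}, 50, sd=0.05)
        m1 = train_model(data, algorithm="rf", cv_folds=5, seed=3)
        m2 = train_model(data, algorithm="rf", cv_folds=5, seed=3)
        assert np.array_equal(m1.cv_scores, m2.cv_scores)
        p1, p2 = predict(m1, data), predict(m2, data)
        pd.testing.assert_frame_equal(p1, p2)


class TestEvaluate:
    def test_perfect_probabilities_give_auc_one(self):
        data = labeled_toy({"A": 0.1, "B": 0.3}, 5)
        proba = np.where(
            (data["label"] == "A").to_numpy()[:, None], [1.0, 0.0], [0.0, 1.0]
        )
        res = evaluate_model(stub_model(["A", "B"], proba), data)
        assert res["auc"] == 1.0 and res["accuracy"] == 1.0
        assert np.allclose(res["confusion"].to_numpy(), np.eye(2))

    def test_uniform_probabilities_give_auc_half(self):
        data = labeled_toy({"A": 0.1, "B": 0.3}, 10)
        proba = np.full((len(data), 2), 0.5)
        res = evaluate_model(stub_model(["A", "B"], proba), data)
        assert res["auc"] == pytest.approx(0.5)

    def test_confusion_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        data = labeled_toy({"A": 0.1, "B": 0.2, "C": 0.3}, 20, sd=0.05)
        proba = rng.dirichlet([1, 1, 1], len(data))
        res = evaluate_model(stub_model(["A", "B", "C"], proba), data)
        assert np.allclose(res["confusion"].sum(axis=1), 1.0)

    def test_single_class_data_rejected(self):
        data = labeled_toy({"A": 0.1}, 10)
        with pytest.raises(ValueError, match="2 classes"):
            evaluate_model(stub_model(["A", "B"], np.ones((10, 2)) / 2), data)

    def test_macro_ovr_auc_matches_pairwise_ranking_oracle(self):
        # 3 events, hand-built probabilities; macro OvR AUC by enumeration
        data = labeled_toy({"A": 0.1, "B": 0.2, "C": 0.3}, 1)
        proba = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3], [0.25, 0.25, 0.5]])
        res = evaluate_model(stub_model(["A", "B", "C"], proba), data)

        def ovr_auc(scores, positives):
            pos = [s for s, p in zip(scores, positives) if p]
            neg = [s for s, p in zip(scores, positives) if not p]
            pairs = [(1.0 if a > b else 0.5 if a == b else 0.0) for a in pos for b in neg]
            return float(np.mean(pairs))

        y = data["label"].to_numpy()
        expected = np.mean(
            [ovr_auc(proba[:, i], y == c) for i, c in enumerate(["A", "B", "C"])]
        )
        assert res["auc"] == pytest.approx(expected)


class TestThresholdCurve:
    def test_zero_threshold_keeps_everything(self):
        data = labeled_toy({"A": 0.1, "B": 0.3}, 10)
        proba = np.tile([0.7, 0.3], (len(data), 1))
        model = stub_model(["A", "B"], proba)
        curve = threshold_curve(model, data, thresholds=np.array([0.0]))
        assert curve.loc[0, "retained_fraction"] == 1.0
        overall = evaluate_model(model, data)["accuracy"]
        assert curve.loc[0, "accuracy"] == pytest.approx(overall)

    def test_unit_threshold_keeps_only_unanimous_calls(self):
        data = labeled_toy({"A": 0.1, "B": 0.3}, 2)
        proba = np.array([[1.0, 0.0], [0.6, 0.4], [0.0, 1.0], [0.55, 0.45]])
        curve = threshold_curve(stub_model(["A", "B"], proba), data,
                                thresholds=np.array([1.0]))
        assert curve.loc[0, "retained_fraction"] == pytest.approx(0.5)


class TestPredict:
    def test_probabilities_sum_to_one_and_empty_input_ok(self):
        data = labeled_toy({"A": 0.1, "B": 0.3}, 40)
        model = train_model(data, algorithm="rf", cv_folds=5, seed=0)
        pred = predict(model, data)
        assert np.allclose(pred[model.classes].sum(axis=1), 1.0, atol=1e-9)
        empty = predict(model, data.iloc[:0])
        assert len(empty) == 0 and list(empty.columns) == list(pred.columns)

    def test_schema_mismatch_rejected(self):
        data = labeled_toy({"A": 0.1, "B": 0.3}, 30)
        model = train_model(data, algorithm="rf", cv_folds=5, seed=0)
        with pytest.raises(ValueError, match="missing"):
            predict(model, data.drop(columns=["blockade"]))

    def test_centroid_event_called_as_its_class(self):
        data = labeled_toy({"A": 0.10, "B": 0.30}, 50, sd=0.003)
        model = train_model(data, algorithm="rf", cv_folds=5, seed=0)
        centroid = toy_feature_frame(np.array([0.10]))
        assert predict(model, centroid)["call"].iloc[0] == "A"


class TestFeatureImportance:
    def test_blockade_and_nearby_density_features_dominate(self):
        data = labeled_toy({"A": 0.12, "B": 0.25}, 80, sd=0.003)
        model = train_model(data, algorithm="rf", cv_folds=5, seed=0)
        imp = feature_importance(model)
        assert (imp >= 0).all() and len(imp) == len(FEATURE_COLUMNS)
        # the discriminating features are the blockade itself and density
        # features near the two standardized event levels (0.88 and 0.75);
        # every top-10 feature must be one of those
        informative = {"blockade"} | {
            f"X{i:04d}" for i in range(1, 1001)
            if abs(i * 0.001 - 0.88) < 0.05 or abs(i * 0.001 - 0.75) < 0.05
        }
        assert set(imp.index[:10]) <= informative

    def test_unsupported_algorithm_signaled(self):
        data = labeled_toy({"A": 0.1, "B": 0.3}, 30)
        model = train_model(data, algorithm="nb", cv_folds=3, seed=0)
        with pytest.raises(ValueError, match="importance"):
            feature_importance(model)


class TestPersistence:
    def test_model_round_trip(self, tmp_path):
        data = labeled_toy({"A": 0.1, "B": 0.3}, 40)
        model = train_model(data, algorithm="rf", cv_folds=5, seed=0)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        pd.testing.assert_frame_equal(predict(model, data), predict(loaded, data))


class TestOnSimulatedEvents:
    def test_four_class_pipeline_reaches_near_perfect_validation(
        self, labeled_events_4class
    ):
        train, test, val = assemble_datasets(
            labeled_events_4class, SplitSpec(per_class_target=400, seed=0)
        )
        model = train_model(train, algorithm="rf", cv_folds=5, seed=0)
        res = evaluate_model(model, val)
        assert res["auc"] >= 0.99
        assert res["accuracy"] >= 0.99

    def test_mixture_call_proportions_match_truth(self, labeled_events_4class):
        from cupore.params import DEFAULT_PARAMS
        from cupore.signals import detect_events, events_to_frame
        from cupore.simulate import TraceConfig, simulate_trace

        train, _, _ = assemble_datasets(
            labeled_events_4class, SplitSpec(per_class_target=400, seed=0)
        )
        model = train_model(train, algorithm="rf", cv_folds=5, seed=0)
        analytes = [(DEFAULT_PARAMS["S"], 240.0), (DEFAULT_PARAMS["P-S"], 530.0)]
        cfg = TraceConfig.fast(duration=120.0, seed=77)
        trace, log = simulate_trace(analytes, cfg)
        events, _, _ = detect_events(trace, experiment_id="mix")
        df = events_to_frame(events, trace.sampling_rate)
        pred = predict(model, df)
        got = (pred["call"] == "S").mean()
        truth = (log["label"] == "S").mean()
        se = np.sqrt(truth * (1 - truth) / len(log))
        assert abs(got - truth) < 3 * se + 0.03
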