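"""Multi-class amino-acid classification from event feature matrices.

The feature matrix holds one row per translocation event and 1,003
columns: blockade, dwell time, level s.d. and the 1,000 density features
X0001-X1000.  Six classifier families are supported (random forest, naive
Bayes, a single-hidden-layer neural network, k-nearest neighbours, bagged
decision trees and AdaBoost); each is fitted with ten-fold
cross-validation and emits per-event class probabilities, from which the
accuracy/recovery trade-off of a probability threshold can be traced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import accuracy_score, confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .signals import FEATURE_NAMES

__all__ = [
    "FEATURE_COLUMNS",
    "ALGORITHMS",
    "SplitSpec",
    "TrainedModel",
    "assemble_datasets",
    "train_model",
    "evaluate_model",
    "threshold_curve",
    "predict",
    "feature_importance",
    "save_model",
    "load_model",
]

#: The fixed 1,003-column feature schema.
FEATURE_COLUMNS = ["blockade", "dwell_ms", "level_sd", *FEATURE_NAMES]

ALGORITHMS = ("rf", "nb", "nnet", "knn", "bagged_cart", "adaboost")


@dataclass(frozen=True)
class SplitSpec:
    """How to split labeled events into train/test/validation sets.

    One whole experiment per class is held out as validation; of the
    remaining events, ``train_fraction`` (per class) go to training and the
    rest to test.  Training classes are then resampled to exactly
    ``per_class_target`` rows — upsampling with replacement below the
    target, downsampling without replacement above it.
    """

    validation_experiments: dict[str, str] | None = None  # class -> experiment_id
    train_fraction: float = 0.8
    per_class_target: int = 1000
    seed: int | None = None


def assemble_datasets(
    events: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split labeled events into (train, test, validation) matrices."""
    if "label" not in events.columns or "experiment_id" not in events.columns:
        raise ValueError("events must carry 'label' and 'experiment_id' columns")
    rng = np.random.default_rng(spec.seed)
    train_parts, test_parts, val_parts = [], [], []
    for cls, grp in events.groupby("label", sort=True):
        exps = sorted(grp["experiment_id"].unique())
        if len(exps) < 2:
            raise ValueError(
                f"class {cls!r} has a single experiment; no held-out validation possible"
            )
        if spec.validation_experiments and cls in spec.validation_experiments:
            val_exp = spec.validation_experiments[cls]
            if val_exp not in exps:
                raise ValueError(f"unknown validation experiment {val_exp!r} for {cls!r}")
        else:
            val_exp = exps[rng.integers(len(exps))]
        val_parts.append(grp[grp["experiment_id"] == val_exp])
        rest = grp[grp["experiment_id"] != val_exp]
        idx = rng.permutation(len(rest))
        n_train = int(round(spec.train_fraction * len(rest)))
        train_rows = rest.iloc[idx[:n_train]]
        test_parts.append(rest.iloc[idx[n_train:]])
        # resample to the per-class target
        if len(train_rows) == 0:
            raise ValueError(f"class {cls!r} has no training rows")
        if len(train_rows) < spec.per_class_target:
            extra = rng.choice(len(train_rows), size=spec.per_class_target, replace=True)
            train_rows = train_rows.iloc[extra]
        elif len(train_rows) > spec.per_class_target:
            keep = rng.choice(len(train_rows), size=spec.per_class_target, replace=False)
            train_rows = train_rows.iloc[keep]
        train_parts.append(train_rows)
    train = pd.concat(train_parts).reset_index(drop=True)
    test = pd.concat(test_parts).reset_index(drop=True)
    validation = pd.concat(val_parts).reset_index(drop=True)
    return train, test, validation


def _make_estimator(algorithm: str, seed: int | None):
    if algorithm == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    if algorithm == "nb":
        return GaussianNB()
    if algorithm == "nnet":
        # single hidden layer sized ~ sqrt(n_features)
        hidden = max(4, int(round(np.sqrt(len(FEATURE_COLUMNS)))))
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=(hidden,),
                        max_iter=500,
                        random_state=seed,
                    ),
                ),
            ]
        )
    if algorithm == "knn":
        return Pipeline(
            [("scale", StandardScaler()), ("knn", KNeighborsClassifier(n_neighbors=5))]
        )
    if algorithm == "bagged_cart":
        return BaggingClassifier(
            DecisionTreeClassifier(random_state=seed),
            n_estimators=50,
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "adaboost":
        return AdaBoostClassifier(
            DecisionTreeClassifier(max_depth=3, random_state=seed),
            n_estimators=100,
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reuse it reproducibly."""

    algorithm: str
    estimator: object
    classes: list[str]
    feature_columns: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))
    cv_scores: np.ndarray | None = None
    seed: int | None = None

    @property
    def schema_hash(self) -> str:
        payload = json.dumps([self.feature_columns, self.classes]).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _check_schema(model: TrainedModel, data: pd.DataFrame) -> np.ndarray:
    missing = [c for c in model.feature_columns if c not in data.columns]
    if missing:
        raise ValueError(f"feature columns missing from data: {missing[:5]}")
    return data[model.feature_columns].to_numpy(dtype=np.float64)


def train_model(
    train: pd.DataFrame,
    algorithm: str = "rf",
    cv_folds: int = 10,
    seed: int | None = None,
) -> TrainedModel:
    """Fit one classifier with stratified k-fold cross-validation."""
    y = train["label"].to_numpy()
    classes = sorted(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    counts = train["label"].value_counts()
    if counts.min() < cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} rows < cv_folds={cv_folds}"
        )
    X = train[FEATURE_COLUMNS].to_numpy(dtype=np.float64)
    est = _make_estimator(algorithm, seed)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(est, X, y, cv=cv, scoring="accuracy", n_jobs=1)
    est.fit(X, y)
    return TrainedModel(
        algorithm=algorithm,
        estimator=est,
        classes=[str(c) for c in est.classes_] if hasattr(est, "classes_") else classes,
        cv_scores=scores,
        seed=seed,
    )


def predict(model: TrainedModel, events: pd.DataFrame) -> pd.DataFrame:
    """Per-event class probabilities plus the argmax call.

    Returns a frame with one probability column per class (summing to 1),
    a ``call`` column and a ``p_max`` column.  Empty input gives an empty
    frame with the same columns.
    """
    cols = [*model.classes, "call", "p_max"]
    if len(events) == 0:
        return pd.DataFrame(columns=cols)
    X = _check_schema(model, events)
    proba = model.estimator.predict_proba(X)
    out = pd.DataFrame(proba, columns=model.classes, index=events.index)
    calls = np.asarray(model.classes)[np.argmax(proba, axis=1)]
    out["call"] = calls
    out["p_max"] = proba.max(axis=1)
    return out


def evaluate_model(model: TrainedModel, data: pd.DataFrame) -> dict:
    """Macro one-vs-rest AUC, accuracy and row-normalized confusion matrix."""
    y = data["label"].to_numpy()
    if len(pd.unique(y)) < 2:
        raise ValueError("evaluation requires at least 2 classes in the data")
    pred = predict(model, data)
    proba = pred[model.classes].to_numpy()
    acc = float(accuracy_score(y, pred["call"]))
    if len(model.classes) == 2:
        # binary: one-vs-rest AUCs coincide; sklearn wants the 1-D score
        auc = float(roc_auc_score(y == model.classes[1], proba[:, 1]))
    else:
        auc = float(
            roc_auc_score(
                y, proba, multi_class="ovr", average="macro", labels=model.classes
            )
        )
    cm = confusion_matrix(y, pred["call"], labels=model.classes).astype(float)
    row = cm.sum(axis=1, keepdims=True)
    row[row == 0] = 1.0
    cm_norm = pd.DataFrame(cm / row, index=model.classes, columns=model.classes)
    return {"auc": auc, "accuracy": acc, "confusion": cm_norm, "n": int(len(data))}


def threshold_curve(
    model: TrainedModel,
    data: pd.DataFrame,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Accuracy/recovery trade-off of a max-probability filter.

    For each threshold, events whose maximum class probability is at least
    the threshold are retained; the table reports the retained fraction and
    the accuracy on the retained subset (NaN when nothing is retained).
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0001, 0.05), 3)
    y = data["label"].to_numpy()
    pred = predict(model, data)
    p_max = pred["p_max"].to_numpy()
    correct = (pred["call"].to_numpy() == y).astype(float)
    rows = []
    for t in thresholds:
        keep = p_max >= t
        frac = float(keep.mean()) if len(y) else 0.0
        acc = float(correct[keep].mean()) if keep.any() else float("nan")
        rows.append({"threshold": float(t), "retained_fraction": frac, "accuracy": acc})
    return pd.DataFrame(rows)


def feature_importance(model: TrainedModel) -> pd.Series:
    """Per-feature importance scores (tree ensembles only), descending."""
    est = model.estimator
    if hasattr(est, "feature_importances_"):
        imp = np.asarray(est.feature_importances_)
    elif hasattr(est, "estimators_") and all(
        hasattr(e, "feature_importances_") for e in getattr(est, "estimators_", [])
    ) and len(getattr(est, "estimators_", [])) > 0:
        imp = np.mean([e.feature_importances_ for e in est.estimators_], axis=0)
    else:
        raise ValueError(
            f"algorithm {model.algorithm!r} does not expose feature importances"
        )
    s = pd.Series(imp, index=model.feature_columns)
    return s.sort_values(ascending=False)


def save_model(model: TrainedModel, path) -> None:
    """Persist a model as a versioned archive with its feature-schema hash."""
    payload = {
        "format_version": 1,
        "algorithm": model.algorithm,
        "classes": model.classes,
        "feature_columns": model.feature_columns,
        "schema_hash": model.schema_hash,
        "cv_scores": None if model.cv_scores is None else list(map(float, model.cv_scores)),
        "seed": model.seed,
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError("unsupported model archive version")
    model = TrainedModel(
        algorithm=payload["algorithm"],
        estimator=payload["estimator"],
        classes=payload["classes"],
        feature_columns=payload["feature_columns"],
        cv_scores=None if payload["cv_scores"] is None else np.array(payload["cv_scores"]),
        seed=payload["seed"],
    )
    if model.schema_hash != payload["schema_hash"]:
        raise ValueError("model archive schema hash mismatch")
    return model
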