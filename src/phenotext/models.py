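"""Classifier training, prediction with confidence, and cross-validation.

Four classifier families share one contract over patient vectors: linear
support vector machine, Gaussian naive Bayes, decision tree, and random
forest.  Every prediction carries a per-class probability vector; the
*confidence* of a prediction is the probability of the predicted class.
Naive Bayes, trees and forests expose probabilities natively; the linear
SVM's signed margins are passed through a sigmoid (Platt) transform fitted
on the training data so that all four families satisfy the same contract.

Default hyperparameters (overridable through ModelConfig.hyperparameters):

================  ==========================================================
linear_svm        L2 penalty, C=1, squared hinge; per-feature standardization
                  fitted on training data only (raw counts are not scaled for
                  the other families)
gaussian_nb       var_smoothing=1e-9
decision_tree     unlimited depth, Gini impurity
random_forest     100 trees, unlimited depth, Gini impurity
================  ==========================================================

Everything stochastic is seeded; identical data + config + seed gives
bit-identical predictions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.frozen import FrozenEstimator
from sklearn.model_selection import KFold, LeaveOneOut, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .features import PatientVector, vectors_to_matrix

__all__ = [
    "ALGORITHMS",
    "ModelConfig",
    "CVConfig",
    "TrainedModel",
    "Prediction",
    "CVResult",
    "train",
    "predict",
    "cross_validate",
    "save_model",
    "load_model",
    "export_predictions_csv",
]

ALGORITHMS = ("linear_svm", "gaussian_nb", "decision_tree", "random_forest")

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    algorithm: str = "random_forest"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")


@dataclass(frozen=True)
class CVConfig:
    method: str = "stratified_kfold"
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("kfold", "stratified_kfold", "leave_one_out"):
            raise ValueError(f"unknown CV method {self.method!r}")
        if self.method != "leave_one_out" and self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass(frozen=True)
class Prediction:
    """Predicted class for one patient with valid per-class probabilities.

    confidence == max(class_scores.values()) == class_scores[predicted_label];
    ties in the score vector break toward the earlier class in class-name
    order (sorted), which is documented rather than incidental.
    """

    patient_id: str
    predicted_label: str
    confidence: float
    class_scores: Mapping[str, float]


def _build_estimator(config: ModelConfig):
    hp = dict(config.hyperparameters)
    if config.algorithm == "gaussian_nb":
        return GaussianNB(**hp)
    if config.algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=config.seed, **hp)
    if config.algorithm == "random_forest":
        hp.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=config.seed, **hp)
    # linear_svm: standardize, fit the margin, then calibrate the frozen
    # margin model with a sigmoid on the same training data
    hp.setdefault("C", 1.0)
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", LinearSVC(random_state=config.seed, **hp)),
        ]
    )


@dataclass
class TrainedModel:
    """Fitted classifier plus the feature/class bookkeeping needed to apply it.

    ``feature_names`` pins the coordinate order the model was trained on;
    prediction refuses inputs whose feature space does not match.
    """

    algorithm: str
    estimator: object
    feature_names: list[str]
    class_names: list[str]
    config: ModelConfig

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected vectors of length {len(self.feature_names)}, got shape {X.shape}"
            )
        proba = self.estimator.predict_proba(X)
        order = np.argsort(self.estimator.classes_)  # classes_ already sorted; keep explicit
        return proba[:, order]


def train(
    vectors: Sequence[PatientVector],
    config: ModelConfig,
    feature_names: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit one classifier on labeled patient vectors.

    Requires >= 2 classes and >= 1 example per class; deterministic given
    ``config.seed``.
    """
    unlabeled = [v.patient_id for v in vectors if v.label is None]
    if unlabeled:
        raise ValueError(f"cannot train on unlabeled patients: {unlabeled}")
    lengths = {len(v.values) for v in vectors}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent vector lengths: {sorted(lengths)}")
    X, _ = vectors_to_matrix(vectors)
    y = np.array([v.label for v in vectors])
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError(f"training requires >= 2 classes, got {classes}")

    est = _build_estimator(config)
    est.fit(X, y)
    if config.algorithm == "linear_svm":
        est = CalibratedClassifierCV(FrozenEstimator(est), method="sigmoid").fit(X, y)

    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(X.shape[1])
    ]
    return TrainedModel(config.algorithm, est, names, classes, config)


def predict(model: TrainedModel, vectors: Sequence[PatientVector]) -> list[Prediction]:
    """One Prediction per patient; scores sum to 1, argmax ties break by
    class-name order."""
    X, pids = vectors_to_matrix(vectors)
    proba = model.predict_proba(X)
    out = []
    for pid, row in zip(pids, proba):
        j = int(np.argmax(row))  # first max -> earliest class name wins ties
        scores = {c: float(p) for c, p in zip(model.class_names, row)}
        out.append(Prediction(pid, model.class_names[j], float(row[j]), scores))
    return out


@dataclass(frozen=True)
class CVResult:
    """Out-of-fold predictions: each patient predicted exactly once, by a
    model whose training folds excluded that patient."""

    predictions: list[Prediction]
    fold_of: Mapping[str, int]
    true_labels: Mapping[str, str]

    @property
    def accuracy(self) -> float:
        correct = sum(
            1 for p in self.predictions if p.predicted_label == self.true_labels[p.patient_id]
        )
        return correct / len(self.predictions)


def _splitter(cvconfig: CVConfig):
    if cvconfig.method == "kfold":
        return KFold(cvconfig.n_folds, shuffle=True, random_state=cvconfig.seed)
    if cvconfig.method == "stratified_kfold":
        return StratifiedKFold(cvconfig.n_folds, shuffle=True, random_state=cvconfig.seed)
    return LeaveOneOut()


def cross_validate(
    vectors: Sequence[PatientVector],
    mconfig: ModelConfig,
    cvconfig: CVConfig,
    feature_names: Sequence[str] | None = None,
) -> CVResult:
    """Patient-level cross-validation (vectors are per-patient, so folds can
    never leak one patient's notes across the train/test boundary)."""
    vectors = sorted(vectors, key=lambda v: v.patient_id)
    y = [v.label for v in vectors]
    if any(lbl is None for lbl in y):
        raise ValueError("cross-validation requires labeled vectors")
    n = len(vectors)
    if cvconfig.method != "leave_one_out":
        if cvconfig.n_folds > n:
            raise ValueError(f"n_folds={cvconfig.n_folds} exceeds {n} patients")
        if cvconfig.method == "stratified_kfold":
            smallest = min(y.count(c) for c in set(y))
            if cvconfig.n_folds > smallest:
                raise ValueError(
                    f"n_folds={cvconfig.n_folds} exceeds smallest class size {smallest}"
                )

    X = np.zeros((n, 1))  # splitter only needs shapes/labels
    preds: list[Prediction] = []
    fold_of: dict[str, int] = {}
    for fold, (train_idx, test_idx) in enumerate(_splitter(cvconfig).split(X, y)):
        assert not set(train_idx) & set(test_idx)
        model = train([vectors[i] for i in train_idx], mconfig, feature_names)
        fold_preds = predict(model, [vectors[i] for i in test_idx])
        preds.extend(fold_preds)
        for i in test_idx:
            fold_of[vectors[i].patient_id] = fold
    preds.sort(key=lambda p: p.patient_id)
    true_labels = {v.patient_id: v.label for v in vectors}  # type: ignore[misc]
    return CVResult(preds, fold_of, true_labels)


def save_model(model: TrainedModel, fs_names: Sequence[str], path: str | Path) -> None:
    """Persist a versioned model file (algorithm, hyperparameters, feature and
    class names, fitted estimator)."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "algorithm": model.algorithm,
        "hyperparameters": dict(model.config.hyperparameters),
        "seed": model.config.seed,
        "feature_names": list(fs_names),
        "class_names": model.class_names,
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path, expected_feature_names: Sequence[str] | None = None) -> TrainedModel:
    """Load a persisted model; refuses to proceed when the stored feature
    names do not match the feature set about to be applied."""
    payload = joblib.load(path)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    if expected_feature_names is not None and list(expected_feature_names) != payload["feature_names"]:
        raise ValueError(
            "feature names in model file do not match supplied feature set: "
            f"{payload['feature_names']} vs {list(expected_feature_names)}"
        )
    config = ModelConfig(payload["algorithm"], payload["hyperparameters"], payload["seed"])
    return TrainedModel(
        payload["algorithm"],
        payload["estimator"],
        payload["feature_names"],
        payload["class_names"],
        config,
    )


def export_predictions_csv(predictions: Sequence[Prediction], path: str | Path) -> None:
    """CSV "patient_id,predicted_label,confidence,<class scores...>"."""
    if not predictions:
        raise ValueError("no predictions to export")
    classes = sorted(predictions[0].class_scores)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "predicted_label", "confidence", *classes])
        for p in predictions:
            w.writerow(
                [p.patient_id, p.predicted_label, repr(p.confidence)]
                + [repr(p.class_scores[c]) for c in classes]
            )
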