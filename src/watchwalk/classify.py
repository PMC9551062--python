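"""Two-stage SVM activity classification of 4-s windows.

Stage one assigns each window to one of six coarse categories: walking with
arm-swing, other complex walking, running, stationary (vehicle travel
included), unspecified arm activities while static, and unspecified arm
activities while walking.  Stage two refines "other complex walking" into
five arm-carriage sub-categories (hands in pocket, texting, phone call,
shoulder bag, briefcase).  Cross-validation is always partitioned at the
subject level — a subject's windows never span the train/validation divide
of any fold — because windows within a subject are strongly correlated and
window-level folds inflate accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

COARSE_LABELS = [
    "walk_armswing",
    "walk_other",
    "running",
    "stationary",
    "arm_activity_static",
    "arm_activity_walking",
]
REFINED_LABELS = ["pocket", "texting", "phonecall", "shoulderbag", "briefcase"]


class TrainingError(ValueError):
    """Training preconditions violated (classes, subjects, leakage)."""


class SchemaError(ValueError):
    """Feature names do not match the fitted model."""


@dataclass
class ClassifierModel:
    """A fitted one-stage SVM with its feature schema and CV metadata."""

    stage: str  # "coarse" | "refined"
    pipeline: Pipeline
    feature_names: list[str]
    classes: list[str]
    cv_fold_accuracy: list[float] = field(default_factory=list)
    cv_predictions: Optional[np.ndarray] = None  # out-of-fold labels
    seed: int = 0
    refined: Optional["ClassifierModel"] = None

    @property
    def cv_accuracy(self) -> float:
        return float(np.mean(self.cv_fold_accuracy)) if self.cv_fold_accuracy else float("nan")

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "ClassifierModel":
        return joblib.load(path)


def subject_folds(subject_ids: Sequence, n_folds: int, seed: int) -> dict:
    """Deterministic subject → fold assignment.

    A function of the sorted unique subject ids and the seed only, so
    shuffling window order can never change fold membership.
    """
    subjects = sorted(set(subject_ids))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    assignment = {}
    for pos, si in enumerate(order):
        assignment[subjects[si]] = pos % n_folds
    return assignment


def _make_pipeline(n_features: int, seed: int) -> Pipeline:
    # medium Gaussian kernel: scale sqrt(n_features) on standardized inputs,
    # i.e. gamma = 1/n_features
    return Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(
            kernel="rbf",
            gamma=1.0 / n_features,
            C=1.0,
            class_weight="balanced",
            random_state=seed,
        )),
    ])


def train(
    X: np.ndarray,
    labels: Sequence[str],
    subject_ids: Sequence,
    feature_names: Sequence[str],
    stage: str = "coarse",
    seed: int = 0,
    n_folds: int = 10,
) -> ClassifierModel:
    """Fit a multi-class RBF SVM with subject-partitioned cross-validation.

    Folds partition subjects, never windows.  With fewer than ``n_folds``
    subjects the fold count shrinks to the subject count.  Every class must
    be present in at least two subjects, otherwise leakage-safe validation
    of that class is impossible.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups = np.asarray(subject_ids)
    if X.shape[0] != len(labels) or len(labels) != len(groups):
        raise TrainingError("X, labels and subject_ids must align")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise TrainingError("training needs at least two classes")
    for c in classes:
        if len(set(groups[labels == c])) < 2:
            raise TrainingError(
                f"class {c!r} present in fewer than two subjects; "
                "subject-partitioned CV would leak"
            )

    n_subjects = len(set(groups))
    k = min(n_folds, n_subjects)
    assignment = subject_folds(groups, k, seed)
    fold_of = np.array([assignment[g] for g in groups])

    fold_acc = []
    oof = np.empty(len(labels), dtype=object)
    for f in range(k):
        va = fold_of == f
        tr = ~va
        if len(set(labels[tr])) < 2 or va.sum() == 0:
            continue
        pipe = _make_pipeline(X.shape[1], seed)
        pipe.fit(X[tr], labels[tr])
        pred = pipe.predict(X[va])
        oof[va] = pred
        fold_acc.append(float(np.mean(pred == labels[va])))

    final = _make_pipeline(X.shape[1], seed)
    final.fit(X, labels)
    return ClassifierModel(
        stage=stage,
        pipeline=final,
        feature_names=list(feature_names),
        classes=classes,
        cv_fold_accuracy=fold_acc,
        cv_predictions=oof,
        seed=seed,
    )


def predict(
    model: ClassifierModel,
    X: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Predict one label per window; with an attached refined model,
    windows labelled ``walk_other`` are cascaded through it and the result
    is returned alongside as refined labels (see :func:`predict_two_stage`
    for the pair)."""
    X = np.asarray(X, dtype=float)
    if feature_names is not None and list(feature_names) != model.feature_names:
        raise SchemaError("feature names do not match the fitted model")
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise SchemaError(
            f"expected {len(model.feature_names)} features, got "
            f"{X.shape[1] if X.ndim == 2 else 'non-2D input'}"
        )
    if X.shape[0] == 0:
        return np.array([], dtype=object)
    return model.pipeline.predict(X).astype(object)


def predict_two_stage(
    coarse: ClassifierModel,
    refined: Optional[ClassifierModel],
    X: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Coarse labels plus refined sub-labels where coarse == walk_other."""
    labels = predict(coarse, X)
    sub = np.full(len(labels), None, dtype=object)
    if refined is not None:
        mask = labels == "walk_other"
        if mask.any():
            sub[mask] = predict(refined, np.asarray(X, dtype=float)[mask])
    return labels, sub


@dataclass
class ConfusionReport:
    """Confusion counts with per-class sensitivity and precision (%).

    Sensitivity: correctly identified windows over all windows that truly
    belong to the class (row-normalised diagonal).  Precision: correctly
    identified windows over all windows predicted as the class
    (column-normalised diagonal).  A class absent from the truth has null
    sensitivity; absent from the predictions, null precision.
    """

    classes: list[str]
    counts: np.ndarray  # rows = truth, cols = prediction
    sensitivity: dict[str, Optional[float]]
    precision: dict[str, Optional[float]]

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum()) * 100.0


def evaluate(pred: Sequence[str], truth: Sequence[str]) -> ConfusionReport:
    """Confusion matrix and per-class sensitivity/precision in percent."""
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(pred) != len(truth):
        raise ValueError("pred and truth must have equal length")
    classes = sorted(set(truth) | set(pred))
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, pred):
        counts[idx[t], idx[p]] += 1
    sens: dict[str, Optional[float]] = {}
    prec: dict[str, Optional[float]] = {}
    for c in classes:
        i = idx[c]
        row = counts[i].sum()
        col = counts[:, i].sum()
        sens[c] = 100.0 * counts[i, i] / row if row else None
        prec[c] = 100.0 * counts[i, i] / col if col else None
    return ConfusionReport(classes=classes, counts=counts, sensitivity=sens, precision=prec)
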