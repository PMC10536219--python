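"""Pixel-series crop classification and accuracy metrics.

Three classical supervised classifiers operate on the 16-value seasonal
index series of each pixel: a random forest (Gini impurity, 120 trees,
minimum split 2), a linear-kernel SVM (L2 penalty, squared-hinge loss,
C = 1, balanced class weights, up to 10,000 iterations), and quadratic
discriminant analysis (Gaussian class-conditional model, no
hyperparameters).  Hyperparameters are tuned by stratified k-fold
cross-validated grid search.

Evaluation is confusion-matrix based: rows are actual classes, columns
predicted; overall accuracy is the percentage of the diagonal mass,

    OA = 100 * sum_i X_ii / N,

and the per-class F1 is the harmonic mean of precision and recall,

    F1_i = 2 P_i R_i / (P_i + R_i),  P_i = TP_i/(TP_i+FP_i),
                                     R_i = TP_i/(TP_i+FN_i).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

__all__ = [
    "CLASS_ORDER",
    "LabeledDataset",
    "ConfusionMatrix",
    "MetricsReport",
    "ClassifyError",
    "train_rf",
    "train_svm_linear",
    "train_qda",
    "grid_search",
    "confusion",
    "overall_accuracy",
    "f1_per_class",
    "evaluate",
]

#: fixed reporting order of the three target classes
CLASS_ORDER = ("fallow", "soybean", "oat")


class ClassifyError(ValueError):
    """Invalid input to a classification operation."""


@dataclass
class LabeledDataset:
    """Feature matrix of pixel series with class labels and field provenance.

    ``X`` has one row per pixel and one column per seasonal DOY; ``y`` holds
    class labels; ``field_id`` records which field each pixel came from so
    that train/test splits can be made field-disjoint.
    """

    X: np.ndarray
    y: np.ndarray
    field_id: np.ndarray | None = None
    partition: str = "train"
    doys: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ClassifyError("X must be 2-D with one label per row")
        if np.isnan(self.X).any():
            raise ClassifyError("dataset contains missing values")
        if self.field_id is not None:
            self.field_id = np.asarray(self.field_id)
            if len(self.field_id) != len(self.y):
                raise ClassifyError("field_id length mismatch")

    def __len__(self) -> int:
        return len(self.y)

    @classmethod
    def from_series(cls, dataset, partition: str | None = None) -> "LabeledDataset":
        """Build from a :class:`croplab.timeseries.SeriesDataset`."""
        frame = dataset.frame
        if partition is not None:
            frame = frame[frame["partition"] == partition]
        return cls(
            X=frame[dataset.value_columns].to_numpy(float),
            y=frame["class_label"].to_numpy(),
            field_id=frame["field_id"].to_numpy(),
            partition=partition or "all",
            doys=dataset.grid.doys,
        )


def _check_trainable(train: LabeledDataset, min_per_class: int = 1) -> None:
    classes, counts = np.unique(train.y, return_counts=True)
    if len(classes) < 2:
        raise ClassifyError("training data must contain at least 2 classes")
    if counts.min() < min_per_class:
        lacking = classes[counts < min_per_class]
        raise ClassifyError(
            f"classes {lacking.tolist()} have fewer than {min_per_class} samples"
        )


def train_rf(train: LabeledDataset, n_trees: int = 120, seed: int = 0) -> RandomForestClassifier:
    """Random forest: Gini split criterion, ``min_samples_split=2``, 120 trees.

    The random state is fixed so repeated fits on the same data produce
    bit-identical predictions.
    """
    _check_trainable(train)
    model = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        min_samples_split=2,
        random_state=seed,
        n_jobs=1,
    )
    return model.fit(train.X, train.y)


def train_svm_linear(train: LabeledDataset, C: float = 1.0, max_iter: int = 10000) -> LinearSVC:
    """Linear-kernel SVM: L2 penalty, squared-hinge loss, balanced weights."""
    _check_trainable(train)
    model = LinearSVC(
        C=C,
        penalty="l2",
        loss="squared_hinge",
        class_weight="balanced",
        max_iter=max_iter,
    )
    with warnings.catch_warnings():
        # convergence short of max_iter is acceptable; predictions stabilize early
        warnings.simplefilter("ignore")
        return model.fit(train.X, train.y)


def train_qda(train: LabeledDataset, reg_param: float = 1e-4) -> QuadraticDiscriminantAnalysis:
    """Quadratic discriminant analysis (Gaussian class-conditional model).

    ``reg_param`` shrinks each class covariance toward a multiple of the
    identity; the small default keeps the estimate invertible when a class
    has few pixels relative to the 16 features while leaving well-sampled
    fits essentially untouched.
    """
    _check_trainable(train, min_per_class=2)
    model = QuadraticDiscriminantAnalysis(reg_param=reg_param)
    return model.fit(train.X, train.y)


_TRAINERS = {"rf": train_rf, "svm": train_svm_linear, "qda": train_qda}


def grid_search(
    train: LabeledDataset,
    method: str,
    grid: Sequence[Mapping],
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[Mapping, pd.DataFrame]:
    """Stratified k-fold cross-validated accuracy over a parameter grid.

    ``grid`` is a sequence of keyword dictionaries for the trainer named by
    ``method`` ("rf", "svm", or "qda").  Returns the best parameter set —
    the first grid point among ties, a deterministic convention — and the
    full cross-validation curve (one row per grid point).
    """
    if method not in _TRAINERS:
        raise ClassifyError(f"unknown method {method!r}")
    grid = list(grid)
    if not grid:
        raise ClassifyError("empty parameter grid")
    _, counts = np.unique(train.y, return_counts=True)
    if k_folds > counts.min():
        raise ClassifyError(
            f"k_folds={k_folds} exceeds smallest class count {counts.min()}"
        )
    trainer = _TRAINERS[method]
    splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(splitter.split(train.X, train.y))
    rows = []
    for params in grid:
        accs = []
        for tr_idx, va_idx in folds:
            sub = LabeledDataset(train.X[tr_idx], train.y[tr_idx])
            model = trainer(sub, **params)
            accs.append(float(np.mean(model.predict(train.X[va_idx]) == train.y[va_idx])))
        rows.append({**params, "cv_accuracy": float(np.mean(accs))})
    curve = pd.DataFrame(rows)
    best = grid[int(np.argmax(curve["cv_accuracy"].to_numpy()))]
    return best, curve


# --- confusion matrix and metrics -------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of actual (rows) versus predicted (columns) classes."""

    counts: np.ndarray
    classes: tuple = CLASS_ORDER

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        n = len(self.classes)
        if counts.shape != (n, n):
            raise ClassifyError(f"confusion matrix must be {n}x{n}")
        if np.any(counts < 0):
            raise ClassifyError("confusion counts must be nonnegative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricsReport:
    """Overall accuracy (percent), per-class F1, and the source matrix."""

    oa: float
    f1: dict
    cm: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "oa_percent": self.oa,
            "f1": dict(self.f1),
            "confusion": {
                "classes": list(self.cm.classes),
                "counts": self.cm.counts.tolist(),
            },
        }


def confusion(y_true, y_pred, classes: Sequence[str] = CLASS_ORDER) -> ConfusionMatrix:
    """Count matrix with rows = actual class, columns = predicted class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ClassifyError("label sequences differ in length")
    if len(y_true) == 0:
        raise ClassifyError("empty label sequences")
    index = {c: i for i, c in enumerate(classes)}
    unknown = set(np.unique(y_true)) | set(np.unique(y_pred))
    unknown -= set(classes)
    if unknown:
        raise ClassifyError(f"labels {sorted(unknown)} not in class list {tuple(classes)}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy: 100 * trace / total count, as a percentage."""
    if cm.total == 0:
        raise ClassifyError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def f1_per_class(cm: ConfusionMatrix) -> dict:
    """Per-class F1 from the confusion matrix.

    ``TP_i = X_ii``, ``FN_i = row_i - TP_i``, ``FP_i = col_i - TP_i``; the
    F1 of a class absent from both truth and predictions is 0 by convention
    (a warning is emitted).
    """
    if cm.total == 0:
        raise ClassifyError("empty confusion matrix")
    out = {}
    for i, cls in enumerate(cm.classes):
        tp = float(cm.counts[i, i])
        fn = float(cm.counts[i, :].sum()) - tp
        fp = float(cm.counts[:, i].sum()) - tp
        denom = 2 * tp + fn + fp
        if denom == 0:
            warnings.warn(f"class {cls!r} absent from truth and predictions; F1 set to 0",
                          stacklevel=2)
            out[cls] = 0.0
        else:
            out[cls] = 2 * tp / denom
    return out


def evaluate(model, test: LabeledDataset, classes: Sequence[str] = CLASS_ORDER) -> MetricsReport:
    """Predict on a held-out dataset and compute OA, per-class F1, confusion."""
    y_pred = model.predict(test.X)
    cm = confusion(test.y, y_pred, classes)
    return MetricsReport(oa=overall_accuracy(cm), f1=f1_per_class(cm), cm=cm)
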