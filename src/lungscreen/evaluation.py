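"""Cross-validation protocol, metrics, and error of omission.

Metrics follow the screening study's reporting: overall accuracy plus
macro-averaged precision, recall, and F1, expressed as percentages with
three decimals, aggregated over stratified k-fold cross-validation as
minimum / maximum / average.  The per-class *error of omission* is the
false-negative rate, ``100 * FN_class / n_class``, which is exactly
``100 - recall%`` for that class.

Feature selection, when part of the evaluated pipeline, is refit inside
every fold's training split so no information leaks from the held-out fold.
A ``refit_selection=False`` mode reproduces the select-once-on-all-data
variant for comparison.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .selectors import iterative_select

METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


def compute_metrics(y_true, y_pred, classes=None) -> dict[str, float]:
    """Accuracy and macro precision/recall/F1 as percentages (3 decimals).

    A class present in ``classes`` but absent from ``y_true`` has undefined
    recall; it is scored 0 with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    missing = [c for c in classes if c not in set(y_true.tolist())]
    if missing:
        warnings.warn(f"classes absent from y_true scored 0: {missing}",
                      RuntimeWarning)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, average="macro", zero_division=0)
    acc = float(np.mean(y_true == y_pred))
    return {
        "accuracy": round(100.0 * acc, 3),
        "precision": round(100.0 * float(prec), 3),
        "recall": round(100.0 * float(rec), 3),
        "f1": round(100.0 * float(f1), 3),
    }


def confusion(y_true, y_pred, classes=None) -> np.ndarray:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    return _sk_confusion(y_true, y_pred, labels=np.asarray(classes))


def error_of_omission(y_true, y_pred, class_label) -> float:
    """Percentage of *class_label* samples predicted into other classes."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    in_class = y_true == class_label
    n_class = int(in_class.sum())
    if n_class == 0:
        raise ValidationError(f"class {class_label!r} absent from y_true")
    fn = int((y_pred[in_class] != class_label).sum())
    return 100.0 * fn / n_class


@dataclass
class EvaluationReport:
    """Per-fold metrics, min/max/average aggregates, pooled confusion matrix,
    and per-class error of omission."""

    per_fold: list[dict[str, float]]
    aggregate: dict[str, dict[str, float]]
    confusion_matrix: np.ndarray
    classes: list[str]
    error_of_omission: dict[str, float]
    config_fingerprint: str = ""
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "aggregate": self.aggregate,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "classes": list(self.classes),
            "error_of_omission": self.error_of_omission,
            "config_fingerprint": self.config_fingerprint,
            "extra": self.extra,
        }

    def table(self) -> str:
        """Text table in the min/max/average-per-metric layout."""
        lines = [f"{'Statistic':<10}" + "".join(f"{m:>12}" for m in METRIC_NAMES)]
        for stat in ("min", "max", "avg"):
            lines.append(f"{stat:<10}" + "".join(
                f"{self.aggregate[m][stat]:>12.3f}" for m in METRIC_NAMES))
        return "\n".join(lines)


def fingerprint(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _aggregate(per_fold: list[dict[str, float]]) -> dict[str, dict[str, float]]:
    agg = {}
    for m in METRIC_NAMES:
        vals = np.array([f[m] for f in per_fold])
        agg[m] = {"min": round(float(vals.min()), 3),
                  "max": round(float(vals.max()), 3),
                  "avg": round(float(vals.mean()), 3)}
    return agg


def kfold_cv(model_factory: Callable[[], object], X: np.ndarray, y: np.ndarray,
             k: int = 10, seed: int = 0,
             selector: dict | None = None,
             refit_selection: bool = True) -> EvaluationReport:
    """Stratified k-fold cross-validation of a classification head.

    ``model_factory`` returns a fresh unfitted head per fold.  If *selector*
    is given (kwargs for :func:`lungscreen.selectors.iterative_select`, at
    least ``{"method": ...}``), feature selection runs inside each fold's
    training split (default) or once on the full data when
    ``refit_selection=False``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValidationError(
            f"smallest class has {counts.min()} samples; cannot stratify into {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold: list[dict[str, float]] = []
    cm = np.zeros((classes.size, classes.size), dtype=int)
    global_indices = None
    if selector is not None and not refit_selection:
        sel = iterative_select(X=X, y=y, seed=seed, **selector)
        global_indices = sel.chosen_indices
    fold_info = []
    for train_idx, test_idx in skf.split(X, y):
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_te, y_te = X[test_idx], y[test_idx]
        if selector is not None and refit_selection:
            sel = iterative_select(X=X_tr, y=y_tr, seed=seed, **selector)
            cols = sel.chosen_indices
        elif global_indices is not None:
            cols = global_indices
        else:
            cols = slice(None)
        model = model_factory()
        model.fit(X_tr[:, cols], y_tr)
        y_hat = model.predict(X_te[:, cols])
        per_fold.append(compute_metrics(y_te, y_hat, classes=classes))
        cm += confusion(y_te, y_hat, classes=classes)
        fold_info.append({"n_test": int(test_idx.size)})
    eoo = {
        str(c): round(100.0 * (cm[i].sum() - cm[i, i]) / cm[i].sum(), 3)
        for i, c in enumerate(classes)
    }
    cfg = {"k": k, "seed": seed, "selector": selector,
           "refit_selection": refit_selection, "n": int(X.shape[0]),
           "d": int(X.shape[1])}
    return EvaluationReport(
        per_fold=per_fold,
        aggregate=_aggregate(per_fold),
        confusion_matrix=cm,
        classes=[str(c) for c in classes],
        error_of_omission=eoo,
        config_fingerprint=fingerprint(cfg),
        extra={"folds": fold_info},
    )


def evaluate_holdout(model, X_test: np.ndarray, y_test: np.ndarray
                     ) -> EvaluationReport:
    """Single-split evaluation on a held-out test set (one 'fold')."""
    y_hat = model.predict(X_test)
    classes = np.unique(y_test)
    metrics = compute_metrics(y_test, y_hat, classes=classes)
    cm = confusion(y_test, y_hat, classes=classes)
    eoo = {str(c): round(error_of_omission(y_test, y_hat, c), 3) for c in classes}
    return EvaluationReport(
        per_fold=[metrics],
        aggregate=_aggregate([metrics]),
        confusion_matrix=cm,
        classes=[str(c) for c in classes],
        error_of_omission=eoo,
    )
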