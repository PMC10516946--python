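"""Cross-validated evaluation: splits, metrics, confusion matrix, ROC.

Implements the full reporting protocol for the 4-class severity grading
task: stratified 5-fold cross-validation in which each fold's held-out 20%
is the test set and the remainder is split 7:1 into train and validation
(the 70/10/20 convention); per-class precision, recall, F1 and one-vs-rest
AUC; *support-weighted* totals (the convention under which the per-class
rows reproduce the printed totals); overall accuracy; a row-normalized
confusion matrix whose diagonal equals per-class recall; and the
within-±1-grade agreement read off the tridiagonal band.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_curve, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "FoldAssignment",
    "ConfusionMatrix",
    "MetricsReport",
    "split_dataset",
    "confusion",
    "per_class_metrics",
    "weighted_totals",
    "roc_auc_ovr",
    "row_normalize",
    "within_k_agreement",
    "cross_validate",
]

N_CLASSES = 4


@dataclass
class FoldAssignment:
    """5-fold partition: per record, a fold index and a role within the fold.

    ``fold[i]`` is the fold whose *test* set record ``i`` belongs to;
    ``roles[f][i]`` in {"train", "val", "test"} gives record ``i``'s role
    when fold ``f`` is evaluated.
    """

    fold: np.ndarray
    roles: list[np.ndarray]
    seed: int
    n_folds: int = 5


@dataclass
class ConfusionMatrix:
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be non-negative 4x4")

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / max(self.n, 1))


@dataclass
class MetricsReport:
    """Everything the evaluation protocol reports, per class and pooled."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    auc: np.ndarray
    supports: np.ndarray
    totals: dict  # support-weighted totals + accuracy
    confusion: ConfusionMatrix
    within1_per_class: np.ndarray
    within1_overall: float
    fold_metrics: list[dict] = field(default_factory=list)
    fold_sd: dict = field(default_factory=dict)
    roc_curves: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def clean(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            return x

        payload = {
            "per_class": {
                "precision": clean(self.precision),
                "recall": clean(self.recall),
                "f1": clean(self.f1),
                "auc": clean(self.auc),
                "support": clean(self.supports),
                "within1": clean(self.within1_per_class),
            },
            "totals": clean(self.totals),
            "within1_overall": float(self.within1_overall),
            "confusion": clean(self.confusion.counts),
            "fold_metrics": clean(self.fold_metrics),
            "fold_sd": clean(self.fold_sd),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def split_dataset(labels, seed: int = 0, n_folds: int = 5,
                  val_fraction: float = 1.0 / 8.0) -> FoldAssignment:
    """Stratified n-fold assignment with a 70/10/20 train/val/test layout.

    Test sets of the folds partition the data (each ~20%); within each fold
    the remaining 80% is split 7:1 into train and validation, stratified.
    """
    labels = np.asarray(labels, dtype=np.int64)
    counts = np.bincount(labels, minlength=N_CLASSES)
    for c in range(N_CLASSES):
        if 0 < counts[c] < n_folds:
            raise ValueError(
                f"class {c} has only {counts[c]} members; "
                f"need >= {n_folds} for {n_folds}-fold stratification"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold = np.empty(len(labels), dtype=np.int64)
    roles = []
    for f, (rest_idx, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold[test_idx] = f
        role = np.empty(len(labels), dtype=object)
        role[test_idx] = "test"
        n_val = max(int(round(len(rest_idx) * val_fraction)), 1)
        stratify = (
            labels[rest_idx]
            if n_val >= len(np.unique(labels[rest_idx]))
            else None  # too few validation slots to stratify
        )
        tr, va = train_test_split(
            rest_idx,
            test_size=n_val,
            random_state=seed * n_folds + f,
            stratify=stratify,
        )
        role[tr] = "train"
        role[va] = "val"
        roles.append(role)
    return FoldAssignment(fold=fold, roles=roles, seed=seed, n_folds=n_folds)


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """4x4 counts; rows are ground truth, columns are predictions."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if len(arr) and (arr.min() < 0 or arr.max() >= N_CLASSES):
            raise ValueError(f"{name} contains labels outside 0..{N_CLASSES - 1}")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return ConfusionMatrix(cm)


def per_class_metrics(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class (precision, recall, F1) from the confusion matrix.

    Degenerate classes (empty row or column) score 0 with a warning.
    """
    counts = cm.counts
    tp = np.diag(counts).astype(np.float64)
    col = counts.sum(axis=0).astype(np.float64)
    row = counts.sum(axis=1).astype(np.float64)
    if (col == 0).any() or (row == 0).any():
        warnings.warn("empty class row/column; affected metrics reported as 0",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / col, 0.0)
        recall = np.where(row > 0, tp / row, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return precision, recall, f1


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    if precision + recall <= 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def weighted_totals(per_class: np.ndarray, supports: np.ndarray) -> float:
    """Support-weighted mean: ``sum(m_c * s_c) / sum(s_c)``."""
    per_class = np.asarray(per_class, dtype=np.float64)
    supports = np.asarray(supports, dtype=np.float64)
    total = supports.sum()
    if total <= 0:
        raise ValueError("zero total support")
    return float((per_class * supports).sum() / total)


def roc_auc_ovr(y_true, probs) -> tuple[np.ndarray, dict]:
    """One-vs-rest AUC per class (midrank ties) plus ROC curve points.

    Classes absent from ``y_true`` get ``nan`` AUC and are flagged.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[1] != N_CLASSES:
        raise ValueError("probs must be (n, 4)")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("probability rows must sum to 1")
    aucs = np.full(N_CLASSES, np.nan)
    curves = {}
    for c in range(N_CLASSES):
        pos = y_true == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {c} absent (or exclusive); AUC undefined",
                          stacklevel=2)
            continue
        aucs[c] = roc_auc_score(pos, probs[:, c])
        fpr, tpr, thr = roc_curve(pos, probs[:, c])
        curves[c] = {"fpr": fpr, "tpr": tpr, "thresholds": thr}
    return aucs, curves


def row_normalize(cm: ConfusionMatrix) -> np.ndarray:
    """Rows divided by their sums; the diagonal is the per-class recall."""
    counts = cm.counts.astype(np.float64)
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        out = np.where(row > 0, counts / row, 0.0)
    _, recall, _ = per_class_metrics(cm)
    assert np.allclose(np.diag(out), recall)
    return out


def within_k_agreement(cm: ConfusionMatrix, k: int = 1) -> tuple[np.ndarray, float]:
    """Fraction of predictions within ``k`` grades of truth, per class + overall."""
    if k < 0:
        raise ValueError("k must be >= 0")
    counts = cm.counts.astype(np.float64)
    i, j = np.indices(counts.shape)
    band = np.abs(i - j) <= k
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_class = np.where(row > 0, (counts * band).sum(axis=1) / row, 0.0)
    overall = float((counts * band).sum() / max(counts.sum(), 1))
    return per_class, overall


def report_from_predictions(y_true, y_pred, probs,
                            fold_metrics: list[dict] | None = None) -> MetricsReport:
    """Assemble the full report from pooled predictions."""
    cm = confusion(y_true, y_pred)
    precision, recall, f1 = per_class_metrics(cm)
    aucs, curves = roc_auc_ovr(y_true, probs)
    supports = cm.supports
    totals = {
        "precision": weighted_totals(precision, supports),
        "recall": weighted_totals(recall, supports),
        "f1": weighted_totals(f1, supports),
        "auc": weighted_totals(np.nan_to_num(aucs), supports),
        "accuracy": cm.accuracy,
    }
    w1_class, w1_all = within_k_agreement(cm, k=1)
    fold_metrics = fold_metrics or []
    fold_sd = {}
    if fold_metrics:
        for key in ("precision", "recall", "f1", "accuracy"):
            vals = [m[key] for m in fold_metrics if key in m]
            if len(vals) > 1:
                fold_sd[key] = float(np.std(vals, ddof=1))
    return MetricsReport(
        precision=precision, recall=recall, f1=f1, auc=aucs, supports=supports,
        totals=totals, confusion=cm, within1_per_class=w1_class,
        within1_overall=w1_all, fold_metrics=fold_metrics, fold_sd=fold_sd,
        roc_curves=curves,
    )


def cross_validate(
    views: np.ndarray,
    labels: np.ndarray,
    folds: FoldAssignment,
    train_config,
) -> MetricsReport:
    """Train per fold on pre-rendered views, evaluate on each test fold.

    ``views`` is the full ``(N, V, C, H, W)`` tensor; test predictions are
    pooled across folds for the headline report, and per-fold metrics with
    across-fold SD are attached.
    """
    from .model import train as train_model, _softmax

    labels = np.asarray(labels, dtype=np.int64)
    n = len(labels)
    y_pred = np.empty(n, dtype=np.int64)
    all_probs = np.empty((n, N_CLASSES))
    fold_metrics = []
    for f in range(folds.n_folds):
        role = folds.roles[f]
        tr = np.nonzero(role == "train")[0]
        va = np.nonzero(role == "val")[0]
        te = np.nonzero(role == "test")[0]
        model, _ = train_model(
            views[tr], labels[tr], views[va], labels[va], train_config
        )
        v = views.shape[1]
        for start in range(0, len(te), 16):
            idx = te[start : start + 16]
            xb = views[idx].reshape(-1, *views.shape[2:])
            logits, _, _ = model.forward(xb, v)
            p = _softmax(logits, axis=1)
            all_probs[idx] = p
            y_pred[idx] = p.argmax(axis=1)
        cm_f = confusion(labels[te], y_pred[te])
        pf, rf, f1f = per_class_metrics(cm_f)
        fold_metrics.append({
            "fold": f,
            "precision": weighted_totals(pf, cm_f.supports),
            "recall": weighted_totals(rf, cm_f.supports),
            "f1": weighted_totals(f1f, cm_f.supports),
            "accuracy": cm_f.accuracy,
        })
    return report_from_predictions(labels, y_pred, all_probs, fold_metrics)
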