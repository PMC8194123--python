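"""Macro-averaged multi-label metrics, five-fold CV and diagnostics.

Macro-recall and macro-precision average the per-type recall/precision over
interaction types, weighting every type equally; macro-F1 is the harmonic
mean of macro-precision and macro-recall (note: this is *not* the average of
per-type F1 scores, although the two coincide in symmetric cases).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import KFold, StratifiedKFold

from .correlation import euclidean_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MacroMetrics",
    "confusion_counts",
    "macro_metrics",
    "fivefold_cv",
    "compare_methods",
    "neighbor_consistency",
    "format_percent",
]


@dataclass
class ConfusionCounts:
    """Per-type TP/FP/FN/TN counts over a set of evaluated pairs."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if (arr < 0).any():
                raise ValueError("confusion counts must be non-negative")
            setattr(self, name, arr)
        if not (self.tp.shape == self.fp.shape == self.fn.shape == self.tn.shape):
            raise ValueError("count vectors must share one shape")

    @property
    def n_types(self) -> int:
        return self.tp.shape[0]


@dataclass
class MacroMetrics:
    macro_recall: float
    macro_precision: float
    macro_f1: float
    per_type_f1: np.ndarray = field(default_factory=lambda: np.array([]))
    fold_id: str = ""


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Multi-label confusion counts from two (n_samples, n_types) 0/1 matrices."""
    t = np.asarray(y_true).astype(bool)
    p = np.asarray(y_pred).astype(bool)
    if t.shape != p.shape or t.ndim != 2:
        raise ValueError("y_true and y_pred must be equal-shape (n, n_types) matrices")
    return ConfusionCounts(
        tp=(t & p).sum(axis=0),
        fp=(~t & p).sum(axis=0),
        fn=(t & ~p).sum(axis=0),
        tn=(~t & ~p).sum(axis=0),
    )


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    # a type with a zero denominator contributes 0 (conservative; logged)
    out = np.zeros(num.shape, dtype=float)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    if (~nz).any():
        logger.debug("%d type(s) with zero denominator scored 0", int((~nz).sum()))
    return out


def macro_metrics(counts: ConfusionCounts, fold_id: str = "") -> MacroMetrics:
    """Macro recall/precision and their harmonic-mean F1, plus per-type F1."""
    if counts.n_types < 1:
        raise ValueError("need at least one type")
    recall = _safe_ratio(counts.tp, counts.tp + counts.fn)
    precision = _safe_ratio(counts.tp, counts.tp + counts.fp)
    macro_r = float(recall.mean())
    macro_p = float(precision.mean())
    macro_f1 = 0.0 if macro_p + macro_r == 0 else 2 * macro_p * macro_r / (macro_p + macro_r)
    per_type_f1 = _safe_ratio(2 * precision * recall, precision + recall)
    return MacroMetrics(
        macro_recall=macro_r,
        macro_precision=macro_p,
        macro_f1=float(macro_f1),
        per_type_f1=per_type_f1,
        fold_id=fold_id,
    )


def format_percent(values: np.ndarray) -> str:
    """Render a per-fold metric vector as ``'xx.x% ± x.x%'`` (sample sd)."""
    values = np.asarray(values, dtype=float)
    mean = 100.0 * values.mean()
    sd = 100.0 * values.std(ddof=1) if values.size > 1 else 0.0
    return f"{mean:.1f}% ± {sd:.1f}%"


def fivefold_cv(estimator, X: np.ndarray, y: np.ndarray, seed: int = 0,
                n_splits: int = 5) -> tuple[list[MacroMetrics], dict]:
    """Five-fold cross-validation of a pair classifier.

    Pairs (not drugs) are partitioned once, stratified by interaction type
    where every type has at least ``n_splits`` pairs; each fold trains a
    fresh clone on the remaining folds and is scored with the macro metrics.

    Returns the per-fold metrics and a summary with mean, sample sd and the
    ``'xx.x% ± x.x%'`` rendering per metric.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() >= n_splits:
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    else:
        logger.warning("some type has < %d pairs; falling back to unstratified folds",
                       n_splits)
        splitter = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds: list[MacroMetrics] = []
    for fold_id, (train, test) in enumerate(splitter.split(X, y)):
        missing = set(classes) - set(y[train])
        if missing:
            warnings.warn(f"fold {fold_id}: training part lacks types {sorted(missing)}")
        model = clone(estimator)
        model.fit(X[train], y[train])
        y_true = _binarize(y[test], classes)
        y_pred = _predicted_matrix(model, X[test], classes)
        folds.append(macro_metrics(confusion_counts(y_true, y_pred), fold_id=str(fold_id)))
    summary = {}
    for name in ("macro_f1", "macro_recall", "macro_precision"):
        vals = np.array([getattr(m, name) for m in folds])
        summary[name] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "formatted": format_percent(vals),
        }
    return folds, summary


def _binarize(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    out = np.zeros((len(y), len(classes)), dtype=int)
    index = {c: j for j, c in enumerate(classes)}
    for i, label in enumerate(y):
        out[i, index[label]] = 1
    return out


def _predicted_matrix(model, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Multi-label 0/1 prediction matrix aligned with ``classes``."""
    if hasattr(model, "decide_labels"):
        model_classes = list(model.classes_)
        pred = model.decide_labels(X)
    else:  # plain sklearn classifier: single-label argmax
        model_classes = list(model.classes_)
        hard = model.predict(X)
        pred = np.zeros((len(hard), len(model_classes)), dtype=int)
        for i, label in enumerate(hard):
            pred[i, model_classes.index(label)] = 1
    out = np.zeros((pred.shape[0], len(classes)), dtype=int)
    for j, c in enumerate(classes):
        if c in model_classes:
            out[:, j] = pred[:, model_classes.index(c)]
    return out


def compare_methods(metrics_a: list[MacroMetrics] | np.ndarray,
                    metrics_b: list[MacroMetrics] | np.ndarray,
                    metric: str = "macro_f1") -> float:
    """Paired two-sided t-test on per-fold metric values.

    Folds are paired by the shared partition. Identical fold vectors return
    p = 1.0 (no evidence of any difference).
    """
    a = _fold_vector(metrics_a, metric)
    b = _fold_vector(metrics_b, metric)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length fold vectors with >= 2 folds")
    if np.allclose(a, b):
        return 1.0
    return float(stats.ttest_rel(a, b).pvalue)


def _fold_vector(metrics, metric: str) -> np.ndarray:
    if len(metrics) and isinstance(metrics[0], MacroMetrics):
        return np.array([getattr(m, metric) for m in metrics], dtype=float)
    return np.asarray(metrics, dtype=float)


def neighbor_consistency(predicted_ids: list[str],
                         reference_groups: dict[str, list[str]],
                         concordant_group: str,
                         features: np.ndarray,
                         drug_ids: list[str]) -> float:
    """Fraction of predicted drugs whose nearest training drug is concordant.

    For each predicted drug, its single most similar training drug (under
    the inverse-squared-distance similarity, self-matches excluded, ties
    broken by drug-id order) is found among the union of the reference
    groups; the returned fraction counts predicted drugs whose nearest
    neighbour lies in ``concordant_group``.
    """
    if concordant_group not in reference_groups:
        raise ValueError(f"unknown concordant group {concordant_group!r}")
    if any(len(v) == 0 for v in reference_groups.values()):
        raise ValueError("reference groups must be non-empty")
    members: list[tuple[str, str]] = []  # (drug_id, group), sorted for tie-breaks
    for group, ids in reference_groups.items():
        members.extend((d, group) for d in ids)
    members.sort(key=lambda t: t[0])
    index = {d: i for i, d in enumerate(drug_ids)}
    hits = 0
    for pid in predicted_ids:
        best_sim, best_group = -np.inf, None
        for did, group in members:
            if did == pid:
                continue
            sim = euclidean_similarity(features[index[pid]], features[index[did]])
            if sim > best_sim:
                best_sim, best_group = sim, group
        if best_group is None:
            raise ValueError(f"no training drug available for {pid!r}")
        hits += best_group == concordant_group
    if not predicted_ids:
        raise ValueError("no predicted drugs supplied")
    return hits / len(predicted_ids)
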