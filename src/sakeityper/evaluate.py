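"""Confusion matrices, classification metrics, and ROC analysis.

For a multiclass problem each class is reduced one-vs-rest to (TP, TN, FP,
FN) and the five standard metrics are computed per class:

    precision   = TP / (TP + FP)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    recall      = TP / (TP + FN)        (identical to sensitivity)

The aggregate is an unweighted macro-average over classes by default (micro
and class-weighted modes are selectable); overall accuracy is additionally
reported as trace/total.  Metrics with a zero denominator are reported as
NaN with a warning, never silently as 0.  ROC curves are one-vs-rest per
class with trapezoidal AUROC (ties handled by the threshold sweep, which is
equivalent to the Mann-Whitney midpoint convention), plus a macro-average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve

METRIC_NAMES = ("precision", "accuracy", "sensitivity", "specificity", "recall")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Class-ordered count table; rows are true classes, columns predictions."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


class OneVsRest(NamedTuple):
    tp: int
    tn: int
    fp: int
    fn: int


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str],
) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a class-ordered confusion matrix."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("true and predicted label vectors must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    unknown = (set(true_labels) | set(predicted_labels)) - set(index)
    if unknown:
        raise ValueError(f"labels outside class_order: {sorted(unknown)}")
    k = len(class_order)
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=tuple(class_order), counts=counts)


def one_vs_rest(cm: ConfusionMatrix, cls: str) -> OneVsRest:
    """Reduce a multiclass confusion matrix to (TP, TN, FP, FN) for one class."""
    if cls not in cm.classes:
        raise ValueError(f"class {cls!r} not in {cm.classes}")
    i = cm.classes.index(cls)
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[:, i].sum()) - tp
    fn = int(cm.counts[i, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return OneVsRest(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int, name: str, cls: str) -> float:
    if den == 0:
        warnings.warn(
            f"{name} undefined for class {cls!r} (zero denominator); reported as NaN",
            stacklevel=3,
        )
        return float("nan")
    return num / den


def class_metrics(ovr: OneVsRest, cls: str = "") -> dict[str, float]:
    """The five metrics from one-vs-rest counts."""
    tp, tn, fp, fn = ovr.tp, ovr.tn, ovr.fp, ovr.fn
    sens = _ratio(tp, tp + fn, "sensitivity", cls)
    return {
        "precision": _ratio(tp, tp + fp, "precision", cls),
        "accuracy": _ratio(tp + tn, tp + tn + fp + fn, "accuracy", cls),
        "sensitivity": sens,
        "specificity": _ratio(tn, tn + fp, "specificity", cls),
        "recall": sens,
    }


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and aggregated metrics for one model's predictions."""

    per_class: dict[str, dict[str, float]]
    aggregate: dict[str, float]
    overall_accuracy: float
    aggregation: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_class).T
        df.loc[self.aggregation] = pd.Series(self.aggregate)
        return df


def metrics(cm: ConfusionMatrix, aggregation: str = "macro") -> MetricsReport:
    """Per-class metrics plus an aggregate (macro by default).

    ``macro`` averages per-class metrics unweighted, ``weighted`` weights by
    class support, and ``micro`` pools the one-vs-rest counts before applying
    the formulas.  Classes whose metric is undefined are excluded from macro
    and weighted averages with a warning.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class = {
        cls: class_metrics(one_vs_rest(cm, cls), cls) for cls in cm.classes
    }
    if aggregation == "micro":
        pooled = OneVsRest(
            tp=sum(one_vs_rest(cm, c).tp for c in cm.classes),
            tn=sum(one_vs_rest(cm, c).tn for c in cm.classes),
            fp=sum(one_vs_rest(cm, c).fp for c in cm.classes),
            fn=sum(one_vs_rest(cm, c).fn for c in cm.classes),
        )
        aggregate = class_metrics(pooled, "micro")
    elif aggregation in ("macro", "weighted"):
        support = cm.counts.sum(axis=1).astype(float)
        weights = np.ones(len(cm.classes)) if aggregation == "macro" else support
        aggregate = {}
        for m in METRIC_NAMES:
            vals = np.array([per_class[c][m] for c in cm.classes])
            ok = ~np.isnan(vals)
            if not ok.all():
                warnings.warn(
                    f"{m}: {int((~ok).sum())} class(es) undefined; "
                    f"excluded from {aggregation} average",
                    stacklevel=2,
                )
            aggregate[m] = (
                float(np.average(vals[ok], weights=weights[ok])) if ok.any() else float("nan")
            )
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return MetricsReport(
        per_class=per_class,
        aggregate=aggregate,
        overall_accuracy=float(np.trace(cm.counts)) / cm.total,
        aggregation=aggregation,
    )


@dataclass(frozen=True)
class ROCResult:
    """One-vs-rest ROC curves and AUROC per class, plus the macro average."""

    curves: dict[str, tuple[np.ndarray, np.ndarray]]  # class -> (FPR, TPR)
    auroc: dict[str, float]
    macro_auroc: float

    def points_frame(self) -> pd.DataFrame:
        frames = []
        for cls, (fpr, tpr) in self.curves.items():
            frames.append(pd.DataFrame({"class": cls, "fpr": fpr, "tpr": tpr}))
        return pd.concat(frames, ignore_index=True)


def roc_auc(
    true_labels: Sequence[str],
    per_class_scores: pd.DataFrame,
    class_order: Sequence[str] | None = None,
) -> ROCResult:
    """One-vs-rest ROC per class by threshold sweep; trapezoidal AUROC.

    Classes absent from the true labels have no defined ROC; they are
    excluded from the macro average with a warning.
    """
    true_labels = np.asarray(true_labels)
    classes = list(class_order) if class_order is not None else list(per_class_scores.columns)
    missing = set(classes) - set(per_class_scores.columns)
    if missing:
        raise ValueError(f"score columns missing for classes: {sorted(missing)}")
    if len(true_labels) != len(per_class_scores):
        raise ValueError("labels and score rows must have equal length")
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    aurocs: dict[str, float] = {}
    for cls in classes:
        y = (true_labels == cls).astype(int)
        if y.sum() == 0 or y.sum() == y.size:
            warnings.warn(
                f"AUROC undefined for class {cls!r} (absent positives or negatives); "
                "excluded from macro average",
                stacklevel=2,
            )
            continue
        fpr, tpr, _ = roc_curve(y, per_class_scores[cls].to_numpy())
        curves[cls] = (fpr, tpr)
        aurocs[cls] = float(auc(fpr, tpr))
    macro = float(np.mean(list(aurocs.values()))) if aurocs else float("nan")
    return ROCResult(curves=curves, auroc=aurocs, macro_auroc=macro)
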