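"""Confusion-matrix construction and classification metrics.

Per-class metrics come from the one-vs-rest reduction of the 5x5 confusion
matrix: accuracy ``(TP+TN)/(TP+TN+FP+FN)``, precision ``TP/(TP+FP)``,
recall/sensitivity ``TP/(TP+FN)``, specificity ``TN/(TN+FP)`` and F1 as the
harmonic mean of precision and recall.  Multi-class summaries default to
macro averaging (unweighted over classes); micro and support-weighted
averages are also provided.  A metric with a zero denominator is undefined
(NaN) and is excluded from the macro average with a warning — never
silently treated as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labels import ALL_LABELS, N_CLASSES


class UndefinedMetricError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (5, 5) ints; rows = true class, cols = predicted

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class BinaryMetrics:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float


def confusion_matrix(true_labels, predicted_labels) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    if t.size and (min(t.min(), p.min()) < 0 or max(t.max(), p.max()) >= N_CLASSES):
        raise ValueError(f"labels must lie in 0..{N_CLASSES - 1}")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts=counts)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def binary_metrics(tp: int, tn: int, fp: int, fn: int) -> BinaryMetrics:
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + tn + fp + fn == 0:
        raise UndefinedMetricError("all counts are zero; metrics undefined")
    pre = _safe_div(tp, tp + fp)
    rec = _safe_div(tp, tp + fn)
    f1 = _safe_div(2.0 * pre * rec, pre + rec) if pre == pre and rec == rec else float("nan")
    return BinaryMetrics(
        accuracy=_safe_div(tp + tn, tp + tn + fp + fn),
        precision=pre,
        recall=rec,
        specificity=_safe_div(tn, tn + fp),
        f1=f1,
    )


_METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1")


@dataclass
class MetricReport:
    per_class: pd.DataFrame  # one row per class, metric columns (NaN = undefined)
    macro: dict[str, float]
    micro: dict[str, float]
    weighted: dict[str, float]
    overall_accuracy: float

    def as_percent(self) -> pd.DataFrame:
        return (self.per_class[list(_METRIC_NAMES)] * 100.0).round(2)


def multiclass_report(cm: ConfusionMatrix) -> MetricReport:
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    rows = []
    tps = fps = fns = 0
    support = counts.sum(axis=1)
    for c, lab in enumerate(ALL_LABELS):
        tp = int(counts[c, c])
        fn = int(counts[c].sum() - tp)
        fp = int(counts[:, c].sum() - tp)
        tn = total - tp - fn - fp
        m = binary_metrics(tp, tn, fp, fn)
        rows.append({"class": lab.name, "support": int(support[c]),
                     **{k: getattr(m, k) for k in _METRIC_NAMES}})
        tps += tp
        fps += fp
        fns += fn
    per_class = pd.DataFrame(rows)

    macro: dict[str, float] = {}
    for k in _METRIC_NAMES:
        vals = per_class[k].to_numpy()
        defined = np.isfinite(vals)
        if not defined.all():
            warnings.warn(
                f"{k} undefined for {int((~defined).sum())} class(es); "
                "macro average computed over defined classes"
            )
        macro[k] = float(np.nanmean(vals)) if defined.any() else float("nan")

    micro_pre = _safe_div(tps, tps + fps)
    micro_rec = _safe_div(tps, tps + fns)
    micro = {
        "precision": micro_pre,
        "recall": micro_rec,
        "f1": _safe_div(2 * micro_pre * micro_rec, micro_pre + micro_rec),
        "accuracy": _safe_div(np.trace(counts), total),
        "specificity": float("nan"),
    }
    weighted = {}
    for k in _METRIC_NAMES:
        vals = per_class[k].to_numpy()
        w = support / support.sum()
        defined = np.isfinite(vals)
        weighted[k] = float(np.sum(vals[defined] * w[defined]) / w[defined].sum()) if defined.any() else float("nan")

    return MetricReport(
        per_class=per_class, macro=macro, micro=micro, weighted=weighted,
        overall_accuracy=float(np.trace(counts) / total),
    )
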