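"""One-vs-rest multi-class evaluation: per-class metrics, macro averages,
multi-run aggregation, and ROC/AUC.

Every class in turn is treated as positive and the remaining classes pooled
as negative, giving per-class TP/FP/TN/FN counts from which five metrics are
computed:

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    precision   = TP / (TP + FP)
    specificity = TN / (TN + FP)
    sensitivity = TP / (TP + FN)
    f1          = 2 * precision * sensitivity / (precision + sensitivity)

Macro averages are the unweighted arithmetic means over classes; a zero
denominator yields NaN (with a warning) rather than a silently fabricated
score, and NaN propagates into the macro mean.  Repeated runs are aggregated
by element-wise means of the per-class metrics, with macro averages then
recomputed from the aggregated per-class values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METRIC_NAMES = ["accuracy", "sensitivity", "precision", "specificity", "f1"]


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest counts; arrays indexed by class."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def n_samples(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0])


@dataclass
class MetricsReport:
    """Per-class metric table plus macro averages (values in [0, 1] or NaN)."""

    per_class: pd.DataFrame          # rows: class names, columns: METRIC_NAMES
    macro: pd.Series = field(default=None)
    run_id: str = ""

    def __post_init__(self):
        if self.macro is None:
            self.macro = macro_average(self.per_class)

    @property
    def n_classes(self) -> int:
        return len(self.per_class)

    def to_frame(self) -> pd.DataFrame:
        out = self.per_class.copy()
        out.loc["macro"] = self.macro
        return out

    def to_csv(self, path, decimals: int | None = None) -> None:
        frame = self.to_frame()
        if decimals is not None:
            frame = frame.round(decimals)
        frame.to_csv(path, index_label="class", lineterminator="\n")

    def to_json(self, path) -> None:
        payload = {"run_id": self.run_id,
                   "per_class": self.per_class.to_dict(orient="index"),
                   "macro": self.macro.to_dict()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def confusion_counts(y_true, y_pred, n_classes: int) -> ConfusionCounts:
    """One-vs-rest confusion counts for every class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    tp = np.zeros(n_classes, dtype=int)
    fp = np.zeros(n_classes, dtype=int)
    fn = np.zeros(n_classes, dtype=int)
    for k in range(n_classes):
        tp[k] = np.sum((y_true == k) & (y_pred == k))
        fp[k] = np.sum((y_true != k) & (y_pred == k))
        fn[k] = np.sum((y_true == k) & (y_pred != k))
    tn = len(y_true) - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn)


def _safe_div(num, den, what: str):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full_like(num, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    if not ok.all():
        warnings.warn(f"zero denominator in {what}; reporting NaN")
    return out


def per_class_metrics(counts: ConfusionCounts,
                      class_names: list[str] | None = None) -> pd.DataFrame:
    """The five one-vs-rest metrics for every class."""
    tp, fp, tn, fn = (a.astype(float) for a in (counts.tp, counts.fp, counts.tn, counts.fn))
    accuracy = _safe_div(tp + tn, tp + fp + tn + fn, "accuracy")
    precision = _safe_div(tp, tp + fp, "precision")
    specificity = _safe_div(tn, tn + fp, "specificity")
    sensitivity = _safe_div(tp, tp + fn, "sensitivity")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    if class_names is None:
        class_names = [f"class_{k}" for k in range(counts.n_classes)]
    return pd.DataFrame(
        {"accuracy": accuracy, "sensitivity": sensitivity, "precision": precision,
         "specificity": specificity, "f1": f1},
        index=pd.Index(class_names, name="class"))[METRIC_NAMES]


def macro_average(per_class: pd.DataFrame) -> pd.Series:
    """Unweighted arithmetic mean of each metric over classes (NaN propagates)."""
    if len(per_class) < 1:
        raise ValueError("need at least one class")
    if per_class.isna().any().any():
        warnings.warn("NaN per-class metric propagates into the macro average")
    return per_class.mean(axis=0, skipna=False)


def evaluate(y_true, y_pred, class_names: list[str], run_id: str = "") -> MetricsReport:
    """Convenience wrapper: counts -> per-class metrics -> macro averages."""
    counts = confusion_counts(y_true, y_pred, len(class_names))
    return MetricsReport(per_class_metrics(counts, class_names), run_id=run_id)


def aggregate_runs(reports: list[MetricsReport]) -> MetricsReport:
    """Mean over runs of every per-class metric; macro recomputed afterwards.

    Rounding to the printed two decimals happens only at report-writing time,
    never inside the aggregation.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    index = reports[0].per_class.index
    for r in reports[1:]:
        if not r.per_class.index.equals(index):
            raise ValueError("reports have mismatched class tables")
    stacked = np.stack([r.per_class.values for r in reports])
    mean = pd.DataFrame(stacked.mean(axis=0), index=index, columns=METRIC_NAMES)
    run_id = "+".join(r.run_id for r in reports if r.run_id)
    return MetricsReport(mean, run_id=run_id)


def roc_curve_ovr(scores_k: np.ndarray, positive: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-rest ROC points (FPR, TPR) over all score thresholds.

    Tied scores are grouped into a single threshold step, so the trapezoidal
    area below equals the midpoint (concordance-probability) tie convention.
    """
    order = np.argsort(-scores_k, kind="stable")
    s = scores_k[order]
    pos = positive[order].astype(float)
    tps = np.cumsum(pos)
    fps = np.cumsum(1.0 - pos)
    # keep only the last index of each tied-score group
    last = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tpr = np.r_[0.0, tps[last]] / max(tps[-1], 1.0)
    fpr = np.r_[0.0, fps[last]] / max(fps[-1], 1.0)
    return fpr, tpr


def roc_auc_ovr(scores: np.ndarray, y_true) -> np.ndarray:
    """Per-class one-vs-rest AUC by trapezoidal integration of the ROC."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite scores")
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("scores must be N x m with m >= 2")
    aucs = np.full(scores.shape[1], np.nan)
    for k in range(scores.shape[1]):
        positive = y_true == k
        if positive.all() or not positive.any():
            warnings.warn(f"class {k} absent from one side of y_true; AUC is NaN")
            continue
        fpr, tpr = roc_curve_ovr(scores[:, k], positive)
        aucs[k] = np.trapezoid(tpr, fpr)
    return aucs
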