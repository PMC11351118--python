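"""Classification and transit-time metrics.

Per-organ metrics are one-vs-rest binarizations of the 3x3 confusion
matrix: sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total, error rate 1 - accuracy, the Matthews correlation
coefficient, and the geometric mean sqrt(sensitivity * specificity) — the
latter two chosen because the small intestine dominates capsule video
(70-80% of frames) and plain accuracy hides minority-organ failure.
Overall scores are accuracy, micro-F1 (identically equal to accuracy for
single-label multiclass) and macro-F1.  Transit-time quality is summarized
over videos by the absolute prediction error in minutes plus the fraction
within the clinically motivated 15-minute band, and incomplete-study
agreement by a 2x2 completeness confusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix3",
    "ClassMetrics",
    "MetricsReport",
    "confusion_matrix",
    "per_class_metrics",
    "mcc_one_vs_rest",
    "gmean",
    "overall_scores",
    "metrics_report",
    "transit_error_summary",
    "completeness_confusion",
]

CLASS_NAMES = ("stomach", "small_intestine", "colon")


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 confusion counts; rows = true organ, columns = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("counts must be a non-negative 3x3 matrix")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def binarize(self, organ: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for one-vs-rest on ``organ``."""
        c = self.counts
        tp = int(c[organ, organ])
        fn = int(c[organ].sum() - tp)
        fp = int(c[:, organ].sum() - tp)
        tn = int(c.sum() - tp - fn - fp)
        return tp, fp, fn, tn


def confusion_matrix(
    true_labels: Sequence[int], predicted_labels: Sequence[int]
) -> ConfusionMatrix3:
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("true and predicted label lengths differ")
    if t.size == 0:
        raise ValueError("cannot build a confusion matrix from no labels")
    if ((t < 0) | (t > 2) | (p < 0) | (p > 2)).any():
        raise ValueError("labels must be in {0, 1, 2}")
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix3(counts)


def per_class_metrics(
    cm: ConfusionMatrix3, organ: int
) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, accuracy, error_rate) one-vs-rest.

    A metric whose denominator is empty (e.g. sensitivity of an absent
    class) is reported as NaN rather than 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = cm.binarize(int(organ))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    acc = (tp + tn) / cm.total
    return sens, spec, acc, 1.0 - acc


def mcc_one_vs_rest(cm: ConfusionMatrix3, organ: int) -> float:
    """Binary Matthews correlation coefficient for one organ vs the rest;
    by convention 0 when any denominator factor vanishes."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = cm.binarize(int(organ))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def gmean(sensitivity: float, specificity: float, ndigits: int | None = 3) -> float:
    """Geometric mean sqrt(sensitivity * specificity), rounded to the
    reporting precision (3 decimals by default; ``ndigits=None`` disables)."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    g = math.sqrt(sensitivity * specificity)
    return round(g, ndigits) if ndigits is not None else g


def overall_scores(cm: ConfusionMatrix3) -> tuple[float, float, float]:
    """(accuracy, micro_f1, macro_f1).

    micro-F1 is computed from pooled TP/FP/FN and coincides with accuracy
    for single-label multiclass; macro-F1 averages per-class F1 (a class
    with empty denominator contributes 0).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = float(np.trace(cm.counts)) / cm.total
    tps = fps = fns = 0
    f1s = []
    for organ in range(3):
        tp, fp, fn, _ = cm.binarize(organ)
        tps, fps, fns = tps + tp, fps + fp, fns + fn
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    micro = 2 * tps / (2 * tps + fps + fns)
    return acc, micro, float(np.mean(f1s))


@dataclass(frozen=True)
class ClassMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    error_rate: float
    mcc: float
    gmean: float


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and overall classification metrics for one model."""

    per_class: dict[str, ClassMetrics]
    accuracy: float
    micro_f1: float
    macro_f1: float
    n_frames: int

    def to_dict(self) -> dict:
        return {
            "per_class": {k: vars(v) for k, v in self.per_class.items()},
            "overall": {
                "accuracy": self.accuracy,
                "micro_f1": self.micro_f1,
                "macro_f1": self.macro_f1,
                "n_frames": self.n_frames,
            },
        }

    def summary(self) -> str:
        lines = [
            f"{'Class':<16}{'Sens':>7}{'Spec':>7}{'Acc':>7}{'Err':>7}{'MCC':>7}{'G-mean':>8}"
        ]
        for name, m in self.per_class.items():
            lines.append(
                f"{name:<16}{m.sensitivity:>7.3f}{m.specificity:>7.3f}"
                f"{m.accuracy:>7.3f}{m.error_rate:>7.3f}{m.mcc:>7.3f}{m.gmean:>8.3f}"
            )
        lines.append(
            f"overall: accuracy {self.accuracy:.3f}  micro-F1 {self.micro_f1:.3f}  "
            f"macro-F1 {self.macro_f1:.3f}  (n={self.n_frames})"
        )
        return "\n".join(lines)


def metrics_report(cm: ConfusionMatrix3) -> MetricsReport:
    per_class = {}
    for organ in range(3):
        sens, spec, acc, err = per_class_metrics(cm, organ)
        g = (
            gmean(sens, spec)
            if not (math.isnan(sens) or math.isnan(spec))
            else float("nan")
        )
        per_class[CLASS_NAMES[organ]] = ClassMetrics(
            sensitivity=sens,
            specificity=spec,
            accuracy=acc,
            error_rate=err,
            mcc=mcc_one_vs_rest(cm, organ),
            gmean=g,
        )
    acc, micro, macro = overall_scores(cm)
    return MetricsReport(
        per_class=per_class,
        accuracy=acc,
        micro_f1=micro,
        macro_f1=macro,
        n_frames=cm.total,
    )


# ---------------------------------------------------------------------------
# transit-time evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitErrorSummary:
    """Absolute boundary-time error statistics over videos (minutes)."""

    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    fraction_within_15min: float
    n: int
    n_excluded: int


def transit_error_summary(
    predicted_s: Mapping[str, float | None],
    true_s: Mapping[str, float | None],
) -> tuple[TransitErrorSummary, pd.DataFrame]:
    """Summarize |predicted - true| per video for one boundary type.

    ``predicted_s``/``true_s`` map video id -> boundary timestamp in
    seconds (None when undefined).  Videos where either side is undefined
    are excluded from the statistics and counted; the per-video table also
    carries the signed difference.
    """
    ids = sorted(true_s)
    rows, excluded = [], 0
    for vid in ids:
        t, p = true_s[vid], predicted_s.get(vid)
        if t is None or p is None:
            excluded += 1
            continue
        diff_min = (p - t) / 60.0
        rows.append(
            {
                "video_id": vid,
                "true_s": t,
                "pred_s": p,
                "diff_min": diff_min,
                "abs_diff_min": abs(diff_min),
                "within_15": abs(diff_min) <= 15.0,
            }
        )
    if not rows:
        raise ValueError("no video has both a predicted and a true boundary")
    table = pd.DataFrame(rows)
    a = table["abs_diff_min"].to_numpy()
    summary = TransitErrorSummary(
        mean=float(a.mean()),
        sd=float(a.std(ddof=1)) if a.size > 1 else 0.0,
        median=float(np.median(a)),
        q1=float(np.quantile(a, 0.25)),
        q3=float(np.quantile(a, 0.75)),
        fraction_within_15min=float(table["within_15"].mean()),
        n=len(rows),
        n_excluded=excluded,
    )
    return summary, table


def completeness_confusion(
    predicted_complete: Mapping[str, bool],
    true_complete: Mapping[str, bool],
) -> np.ndarray:
    """2x2 counts of complete/incomplete agreement.

    Rows = truth (complete, incomplete), columns = prediction; entry [0, 1]
    is a missed-complete (capsule reached the colon but the model never saw
    it enter).
    """
    if set(predicted_complete) != set(true_complete):
        raise ValueError("video ids of predictions and truths differ")
    counts = np.zeros((2, 2), dtype=np.int64)
    for vid, truth in true_complete.items():
        counts[0 if truth else 1, 0 if predicted_complete[vid] else 1] += 1
    return counts
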