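"""ROC analysis, Youden-index cutoffs and confusion metrics.

Implements the empirical ROC over midpoint thresholds, trapezoidal AUC,
the Youden-optimal operating point, one-eye-per-subject selection, and
confusion metrics in two modes:

* standard — precision = TP/(TP+FP), F1 = 2PR/(P+R);
* reproduction — the literal definitions used in the source study's
  machine-learning comparison: "precision" := TN/(TN+FP) (numerically the
  specificity), "recall" := TP/(TP+FN) (the sensitivity), and
  F1 := precision*recall/(precision+recall) *without* the factor of 2.
  Only this literal reading reproduces that study's printed F1 values
  (a perfect classifier scores 0.5 in this mode).  The standard metrics
  are always computed alongside; the variant exists for reproduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ROCCurve",
    "YoudenResult",
    "ConfusionMetrics",
    "select_one_eye_per_subject",
    "roc_curve",
    "auc_trapezoid",
    "youden_optimal",
    "choose_orientation",
    "confusion_from_threshold",
    "confusion_metrics_from_counts",
    "metrics_paper_variant",
    "paper_variant_from_rates",
]

HIGHER = "higher_is_positive"
LOWER = "lower_is_positive"


@dataclass(frozen=True)
class ROCCurve:
    thresholds: tuple[float, ...]  # ascending, includes -inf/+inf endpoints
    sensitivity: tuple[float, ...]
    specificity: tuple[float, ...]
    orientation: str
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class YoudenResult:
    cutoff: float
    j_statistic: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    precision_std: float
    f1_std: float
    precision_paper: float
    recall_paper: float
    f1_paper: float


def select_one_eye_per_subject(records):
    """Keep one eye per subject: the right (OD) eye unless the subject only
    contributed a left eye.  Order of subjects is preserved."""
    by_subject: dict[str, list] = {}
    order: list[str] = []
    for rec in records:
        sid = rec.subject_id if hasattr(rec, "subject_id") else rec["subject_id"]
        if sid not in by_subject:
            order.append(sid)
        by_subject.setdefault(sid, []).append(rec)
    out = []
    for sid in order:
        group = by_subject[sid]
        eyes = {(r.eye if hasattr(r, "eye") else r["eye"]) for r in group}
        keep = "OD" if "OD" in eyes else "OS"
        out.extend(r for r in group
                   if (r.eye if hasattr(r, "eye") else r["eye"]) == keep)
    return out


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        y = np.asarray([1 if v in ("ON_POS", "1", 1, True) else 0 for v in y])
    return (np.asarray(y, dtype=float) > 0).astype(int)


def _calls(scores: np.ndarray, threshold: float, orientation: str) -> np.ndarray:
    if orientation == HIGHER:
        return scores > threshold
    return scores < threshold


def roc_curve(scores, labels, orientation: str = HIGHER) -> ROCCurve:
    """Empirical ROC over midpoint thresholds between consecutive distinct
    scores, plus the two infinite endpoints."""
    if orientation not in (HIGHER, LOWER):
        raise ValueError(f"unknown orientation {orientation!r}")
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-math.inf], mids, [math.inf]))
    sens, spec = [], []
    for thr in thresholds:
        call = _calls(s, thr, orientation)
        sens.append(float((call & (y == 1)).sum() / n_pos))
        spec.append(float((~call & (y == 0)).sum() / n_neg))
    return ROCCurve(tuple(thresholds), tuple(sens), tuple(spec),
                    orientation, n_pos, n_neg)


def auc_trapezoid(curve: ROCCurve) -> float:
    """Trapezoidal area under the curve in (1-specificity, sensitivity) space."""
    fpr = 1.0 - np.asarray(curve.specificity)
    tpr = np.asarray(curve.sensitivity)
    order = np.lexsort((tpr, fpr))  # staircase: ties in FPR ordered by TPR
    return float(np.trapezoid(tpr[order], fpr[order]))


def youden_optimal(curve: ROCCurve) -> YoudenResult:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Ties are broken by the smallest finite cutoff; infinite endpoint
    thresholds are only returned when no finite threshold exists.
    """
    thr = np.asarray(curve.thresholds)
    j = np.asarray(curve.sensitivity) + np.asarray(curve.specificity) - 1.0
    finite = np.isfinite(thr)
    if finite.any() and j[finite].max() >= j.max() - 1e-12:
        idx_pool = np.nonzero(finite)[0]
    else:
        idx_pool = np.arange(thr.size)
    best = idx_pool[int(np.argmax(j[idx_pool]))]
    # ascending thresholds -> argmax already picks the smallest cutoff on ties
    return YoudenResult(float(thr[best]), float(j[best]),
                        float(curve.sensitivity[best]), float(curve.specificity[best]))


def choose_orientation(scores, labels) -> str:
    """Orientation for which AUC >= 0.5 (e.g. ON eyes have less-negative
    PhNR, so a higher signed PhNR indicates disease)."""
    auc_hi = auc_trapezoid(roc_curve(scores, labels, HIGHER))
    return HIGHER if auc_hi >= 0.5 else LOWER


def metrics_paper_variant(tp: int, tn: int, fp: int, fn: int):
    """Literal reproduction-mode metrics: precision := TN/(TN+FP),
    recall := TP/(TP+FN), F1 := p*r/(p+r) (no factor of 2).

    Returns (precision_paper, recall_paper, accuracy, f1_paper); a metric
    whose denominator is zero is returned as NaN.
    """
    precision = tn / (tn + fp) if (tn + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    total = tp + tn + fp + fn
    accuracy = (tp + tn) / total if total else float("nan")
    f1 = paper_variant_from_rates(recall, precision)
    return precision, recall, accuracy, f1


def paper_variant_from_rates(sensitivity: float, specificity: float) -> float:
    """Reproduction-mode F1 from an operating point's sensitivity and
    specificity: F1 = (specificity * sensitivity)/(specificity + sensitivity)."""
    denom = specificity + sensitivity
    if not denom or math.isnan(denom):
        return float("nan")
    return specificity * sensitivity / denom


def confusion_metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> ConfusionMetrics:
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else float("nan")
    prec = tp / (tp + fp) if (tp + fp) else float("nan")
    f1 = (2 * prec * sens / (prec + sens)) if (prec + sens) else float("nan")
    p_prec, p_rec, _, p_f1 = metrics_paper_variant(tp, tn, fp, fn)
    return ConfusionMetrics(tp, tn, fp, fn, sens, spec, acc, prec, f1,
                            p_prec, p_rec, p_f1)


def confusion_from_threshold(scores, labels, cutoff: float,
                             orientation: str = HIGHER) -> ConfusionMetrics:
    """Confusion counts and derived metrics at a decision threshold."""
    if orientation not in (HIGHER, LOWER):
        raise ValueError(f"unknown orientation {orientation!r}")
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValueError("confusion metrics require both classes present")
    call = _calls(s, cutoff, orientation)
    tp = int((call & (y == 1)).sum())
    tn = int((~call & (y == 0)).sum())
    fp = int((call & (y == 0)).sum())
    fn = int((~call & (y == 1)).sum())
    return confusion_metrics_from_counts(tp, tn, fp, fn)
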