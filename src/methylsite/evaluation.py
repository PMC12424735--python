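"""Classifier evaluation: PR/ROC geometry and prevalence correction.

Precision measured on a test set with one class imbalance misstates the
precision expected at deployment under another. With the class-conditional
score distributions held fixed, changing the negative:positive ratio from
the test set's r_test to a target r scales the false-positive count by
w = r / r_test, giving the prevalence-corrected precision

    PCPr = TP / (TP + w·FP).

Recall is unaffected. The paper-style use case corrects a 1:6.5 test set to
an assumed 1:36 deployment imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import ValidationError


@dataclass(frozen=True)
class CurvePoint:
    """Confusion counts and derived rates at one score threshold.

    The predicted-positive set is {i : score_i >= threshold}; tied scores
    enter or leave the set together.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else 0.0


@dataclass(frozen=True)
class PrevalenceCorrection:
    """Re-weighting from the test imbalance to a target imbalance."""

    test_neg_pos_ratio: float
    target_neg_pos_ratio: float

    def __post_init__(self) -> None:
        if self.test_neg_pos_ratio <= 0 or self.target_neg_pos_ratio <= 0:
            raise ValidationError("imbalance ratios must be positive")

    @property
    def weight(self) -> float:
        return self.target_neg_pos_ratio / self.test_neg_pos_ratio


@dataclass
class EvalCurves:
    """All distinct-threshold curve points plus the two scalar areas."""

    points: list[CurvePoint]
    auprc: float
    auroc: float


def pr_roc_curves(scores: Sequence[float] | np.ndarray,
                  labels: Sequence[int] | np.ndarray) -> EvalCurves:
    """Curve points over all distinct thresholds, AUPRC and AUROC.

    AUPRC is the step-wise average precision Σ (R_k − R_{k−1})·P_k over
    thresholds in descending order; AUROC is the trapezoidal area under
    (FPR, TPR). Both match exhaustive threshold enumeration exactly.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be equal-length vectors")
    P = int((y == 1).sum())
    N = int((y == 0).sum())
    if P == 0 or N == 0:
        raise ValidationError("both classes must be present")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # group tied scores: cumulative counts at the end of each tie group
    boundary = np.nonzero(np.diff(s_sorted))[0]
    ends = np.append(boundary, len(s_sorted) - 1)
    cum_tp = np.cumsum(y_sorted == 1)[ends]
    cum_fp = np.cumsum(y_sorted == 0)[ends]
    thresholds = s_sorted[ends]

    points = [
        CurvePoint(threshold=float(t), tp=int(tp), fp=int(fp),
                   tn=N - int(fp), fn=P - int(tp))
        for t, tp, fp in zip(thresholds, cum_tp, cum_fp)
    ]

    recall = cum_tp / P
    precision = cum_tp / (cum_tp + cum_fp)
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    auprc = float(np.sum((recall - prev_recall) * precision))

    tpr = np.concatenate([[0.0], recall, [1.0]])
    fpr = np.concatenate([[0.0], cum_fp / N, [1.0]])
    auroc = float(np.trapezoid(tpr, fpr))
    return EvalCurves(points=points, auprc=auprc, auroc=auroc)


def precision_at_recall(curves: EvalCurves | Sequence[CurvePoint],
                        recall_level: float) -> float:
    """Precision at the highest threshold achieving recall ≥ the level."""
    if not 0.0 < recall_level <= 1.0:
        raise ValidationError(f"recall level {recall_level} outside (0, 1]")
    points = curves.points if isinstance(curves, EvalCurves) else list(curves)
    for p in points:  # descending threshold, recall non-decreasing
        if p.recall >= recall_level:
            return p.precision
    raise ValidationError(f"recall level {recall_level} not reachable")


def prevalence_corrected_precision(point: CurvePoint,
                                   correction: PrevalenceCorrection) -> float:
    """PCPr = tp / (tp + w·fp); recall is unchanged by the correction."""
    if point.tp + point.fp == 0:
        raise ValidationError(
            "PCPr undefined with zero predicted positives (not applicable)"
        )
    return point.tp / (point.tp + correction.weight * point.fp)


def threshold_for_target_pcpr(
    curves: EvalCurves | Sequence[CurvePoint],
    correction: PrevalenceCorrection,
    target_pcpr: float,
) -> tuple[float, float, float]:
    """Lowest threshold whose PCPr meets the target (maximizing recall).

    Returns (threshold, achieved PCPr, achieved recall); raises with the
    maximum achievable PCPr when the target cannot be met.
    """
    points = curves.points if isinstance(curves, EvalCurves) else list(curves)
    best = None
    max_pcpr = -1.0
    for p in points:  # descending threshold → ascending recall
        if p.tp + p.fp == 0:
            continue
        pcpr = prevalence_corrected_precision(p, correction)
        max_pcpr = max(max_pcpr, pcpr)
        if pcpr >= target_pcpr:
            best = p  # keep overwriting: later points have lower thresholds
    if best is None:
        raise ValidationError(
            f"target PCPr {target_pcpr} unattainable; maximum achievable is "
            f"{max_pcpr:.4f}"
        )
    return (best.threshold,
            prevalence_corrected_precision(best, correction),
            best.recall)


def imbalance_ratio(n_positive: int, n_negative: int,
                    decimals: int = 1) -> float:
    """Negative:positive ratio, e.g. 4,906/755 → 6.5."""
    if n_positive <= 0:
        raise ValidationError("need at least one positive")
    return round(n_negative / n_positive, decimals)
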