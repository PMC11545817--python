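"""ROC-calibrated per-class thresholds and the argmax-with-rejection rule.

One ROC curve is built per class from the cross-validated predicted values
(PVs) of the training model against the true binary membership.  The
operating threshold maximises Youden's J = sensitivity + specificity - 1
(ties break toward the higher, more specific threshold).  A sample is then
assigned to the class with the highest PV provided that PV strictly exceeds
that class's threshold; otherwise it is rejected as NO_CLASS.  There is no
fallback to the runner-up class when the top class fails its threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import NO_CLASS

logger = logging.getLogger(__name__)


@dataclass
class ROCCurve:
    """Sensitivity/specificity over all candidate thresholds for one class."""

    class_label: str
    thresholds: np.ndarray  # ascending; includes -inf and +inf sentinels
    sensitivity: np.ndarray
    specificity: np.ndarray

    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0

    def auc(self) -> float:
        """Area under sensitivity vs (1 - specificity), by trapezoid.

        Thresholds ascend, so the (fpr, sens) points already trace the curve
        from (1, 1) down to (0, 0); ties produce exact diagonal segments."""
        fpr = 1.0 - self.specificity
        return float(-np.trapezoid(self.sensitivity, fpr))


def roc_curve(pv: np.ndarray, truth: np.ndarray, class_label: str = "") -> ROCCurve:
    """ROC curve for one class from per-sample PVs and binary membership.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted PVs plus -inf/+inf sentinels; a sample is assigned iff its
    PV > threshold.
    """
    pv = np.asarray(pv, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("need both member and non-member samples")
    distinct = np.unique(pv)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        assigned = pv > thr
        sens[i] = np.count_nonzero(assigned & truth) / n_pos
        spec[i] = np.count_nonzero(~assigned & ~truth) / n_neg
    return ROCCurve(class_label, thresholds, sens, spec)


def youden_threshold(curve: ROCCurve) -> float:
    """Threshold maximising J = sensitivity + specificity - 1.

    Ties break toward the higher threshold (the more specific operating
    point)."""
    j = curve.youden()
    best = np.flatnonzero(j == j.max())
    return float(curve.thresholds[best[-1]])


@dataclass
class DecisionRule:
    """Per-class PV thresholds applied on top of the argmax rule."""

    class_labels: tuple[str, ...]
    thresholds: np.ndarray  # one per class

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if len(self.thresholds) != len(self.class_labels):
            raise ValueError("one threshold per class required")


def fit_thresholds(
    cv_pv: np.ndarray, labels: Sequence[str], class_labels: Sequence[str]
) -> DecisionRule:
    """ROC + Youden threshold per class from cross-validated PVs."""
    labels = np.asarray(labels, dtype=object)
    thresholds = np.empty(len(class_labels))
    for j, cls in enumerate(class_labels):
        curve = roc_curve(cv_pv[:, j], labels == cls, class_label=cls)
        thresholds[j] = youden_threshold(curve)
    return DecisionRule(tuple(class_labels), thresholds)


def classify(pv_row: np.ndarray, rule: DecisionRule) -> str:
    """Assign to the argmax-PV class iff that PV strictly exceeds the
    class's own threshold; else NO_CLASS (no runner-up fallback)."""
    pv_row = np.asarray(pv_row, dtype=float)
    if len(pv_row) != len(rule.class_labels):
        raise ValueError("PV row length does not match class count")
    top = np.flatnonzero(pv_row == pv_row.max())
    if len(top) > 1:
        logger.warning("PV tie among classes %s; taking class order",
                       [rule.class_labels[i] for i in top])
    c = int(top[0])
    if pv_row[c] > rule.thresholds[c]:
        return rule.class_labels[c]
    return NO_CLASS


def classify_matrix(pv: np.ndarray, rule: DecisionRule) -> np.ndarray:
    """Vectorised :func:`classify` over the rows of a PV matrix."""
    return np.array([classify(row, rule) for row in np.atleast_2d(pv)], dtype=object)
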