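"""ROC/AUC evaluation, optimal prognostic-index cutoff, confusion-matrix
metrics, and prospective-cohort validation.

AUC is computed as the Mann-Whitney probability that a random case
scores above a random control, ties counted one half; the enumerated ROC
curve's trapezoidal area equals that statistic exactly.  The optimal
cutoff maximizes the unweighted mean of sensitivity and specificity
(equivalent to the Youden index argmax).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .spca_model import RiskModel, prognostic_index

__all__ = [
    "ROCCurve",
    "ContingencyTable",
    "Metrics",
    "roc_and_auc",
    "optimal_cutoff",
    "confusion_metrics",
    "prospective_validate",
]


@dataclass
class ROCCurve:
    """ROC points enumerated at every distinct score.

    A sample is predicted positive when its score is strictly greater
    than the threshold, so the curve runs from (-inf: sensitivity 1,
    specificity 0) to (+inf: sensitivity 0, specificity 1).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    """Proportions in [0, 1]; a ratio with zero denominator is None."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


def _check_binary(labels: pd.Series | np.ndarray) -> np.ndarray:
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def roc_and_auc(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray) -> ROCCurve:
    """ROC curve over all distinct score thresholds plus the AUC.

    The AUC is the Mann-Whitney statistic computed from mid-ranks (tied
    case/control pairs count one half).
    """
    s = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    n_case = int(y.sum())
    n_ctrl = len(y) - n_case

    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_case * (n_case + 1) / 2.0) / (n_case * n_ctrl)

    distinct = np.unique(s)
    thresholds = np.concatenate([[-np.inf], distinct, [np.inf]])
    sens = np.empty(thresholds.shape)
    spec = np.empty(thresholds.shape)
    case_scores = s[y == 1]
    ctrl_scores = s[y == 0]
    for i, t in enumerate(thresholds):
        sens[i] = np.mean(case_scores > t)
        spec[i] = np.mean(ctrl_scores <= t)
    return ROCCurve(
        thresholds=thresholds, sensitivity=sens, specificity=spec, auc=float(auc)
    )


def optimal_cutoff(curve: ROCCurve) -> float:
    """Threshold maximizing mean(sensitivity, specificity).

    Ties are broken toward higher sensitivity, then toward the lower
    threshold, so the result is deterministic even on perfectly
    separated data (where any threshold in the gap is optimal).
    """
    mean_ss = (curve.sensitivity + curve.specificity) / 2.0
    order = np.lexsort(
        (curve.thresholds, -curve.sensitivity, -mean_ss)
    )  # primary: mean desc; then sens desc; then threshold asc
    return float(curve.thresholds[order[0]])


def confusion_metrics(table: ContingencyTable) -> Metrics:
    """Accuracy, sensitivity, specificity, PPV and NPV of a 2x2 table."""
    if table.total == 0:
        raise ValueError("contingency table is empty")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return Metrics(
        accuracy=(table.tp + table.tn) / table.total,
        sensitivity=ratio(table.tp, table.tp + table.fn),
        specificity=ratio(table.tn, table.tn + table.fp),
        ppv=ratio(table.tp, table.tp + table.fp),
        npv=ratio(table.tn, table.tn + table.fn),
    )


def prospective_validate(
    model: RiskModel,
    expression: pd.DataFrame,
    conversion: pd.Series | np.ndarray,
) -> tuple[ContingencyTable, Metrics, pd.Series]:
    """Score a prospective cohort with a fitted model.

    A subject is predicted to convert when the prognostic index is
    strictly greater than the model's cutoff.  Returns the 2x2 table
    of predicted vs observed conversion, its metrics, and the per-sample
    prognostic indices.
    """
    if model.pi_cutoff is None:
        raise ValueError("model has no prognostic-index cutoff; cannot classify")
    pi = prognostic_index(model, expression)
    observed = np.asarray(conversion, dtype=int)
    predicted = (pi.to_numpy() > model.pi_cutoff).astype(int)
    table = ContingencyTable(
        tp=int(np.sum((predicted == 1) & (observed == 1))),
        fp=int(np.sum((predicted == 1) & (observed == 0))),
        fn=int(np.sum((predicted == 0) & (observed == 1))),
        tn=int(np.sum((predicted == 0) & (observed == 0))),
    )
    return table, confusion_metrics(table), pi
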