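"""Classification and regression evaluation statistics, plus the outlier rule.

Classification metrics are defined on raw confusion counts: sensitivity
SE = TP/(TP+FN), specificity SP = TN/(TN+FP), overall accuracy
Q = (TP+TN)/total, and the G-mean sqrt(SE*SP).  Zero denominators raise
:class:`UndefinedMetricError` rather than silently returning 0.

``r2`` here is the squared Pearson correlation; the coefficient of
determination is reported separately as ``r2_cod``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero; the value is undefined, not 0."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching hand-rounded tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total < 1:
            raise ValueError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred, positive) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have the same shape")
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )


def sensitivity(cm: ConfusionCounts) -> float:
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive samples")
    return cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionCounts) -> float:
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative samples")
    return cm.tn / (cm.tn + cm.fp)


def accuracy_q(cm: ConfusionCounts) -> float:
    return (cm.tp + cm.tn) / cm.total


def g_mean(cm: ConfusionCounts) -> float:
    return math.sqrt(sensitivity(cm) * specificity(cm))


def classification_report(cm: ConfusionCounts, ndigits: int = 2) -> dict:
    """All four counts-based metrics, raw and table-rounded."""
    raw = {
        "se": sensitivity(cm),
        "sp": specificity(cm),
        "q": accuracy_q(cm),
        "g_mean": g_mean(cm),
    }
    return {
        "counts": asdict(cm),
        "raw": raw,
        "rounded": {k: round_half_up(v, ndigits) for k, v in raw.items()},
    }


@dataclass(frozen=True)
class RegressionReport:
    r2: float            # squared Pearson correlation
    r2_cod: float        # coefficient of determination
    rmse: float
    mae: float
    pct_abs_err_ge_1: float

    def rounded(self, ndigits: int = 2) -> dict:
        return {k: round_half_up(v, ndigits) for k, v in asdict(self).items()}


def regression_report(y_true, y_pred) -> RegressionReport:
    """RMSE, MAE, squared-Pearson r2 and the share of |error| >= 1."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D arrays of equal length")
    n = y_true.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(y_true) == 0:
        raise UndefinedMetricError("r2 undefined for a constant target")
    err = y_true - y_pred
    if np.ptp(y_pred) == 0:
        r2 = 0.0  # correlation with a constant prediction is undefined; no linear association
    else:
        r2 = float(stats.pearsonr(y_true, y_pred).statistic ** 2)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return RegressionReport(
        r2=r2,
        r2_cod=1.0 - float(np.sum(err**2)) / ss_tot,
        rmse=float(np.sqrt(np.mean(err**2))),
        mae=float(np.mean(np.abs(err))),
        pct_abs_err_ge_1=100.0 * float(np.mean(np.abs(err) >= 1.0)),
    )


def outlier_flags(abs_errors, mae: float, factor: float = 3.0) -> tuple[np.ndarray, float]:
    """Flag predictions with absolute error strictly greater than ``factor * mae``.

    Returns the boolean flag vector and the flagged percentage over all
    samples.  The comparison is strict: an error exactly at the threshold
    is not an outlier.
    """
    abs_errors = np.asarray(abs_errors, dtype=float)
    if not mae > 0:
        raise ValueError(f"mae must be positive, got {mae}")
    if (abs_errors < 0).any():
        raise ValueError("absolute errors must be non-negative")
    flags = abs_errors > factor * mae
    pct = 100.0 * float(flags.mean()) if abs_errors.size else 0.0
    return flags, pct
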