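"""Masked performance metrics and model comparison.

All metrics are computed only over masked-in steps — dose events at which
a trough was actually drawn — and every metric is reported with the
observation count n.  Model comparison uses a two-sided paired t-test on
per-observation absolute errors.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .model import PredictionRecord
from .preprocessing import CLASS_NAMES, trough_class

__all__ = [
    "EvalReport",
    "UndefinedMetricError",
    "rmse",
    "mae",
    "r_squared",
    "paired_t_mae",
    "agreement_report",
    "evaluate_predictions",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined for the given inputs (empty mask, zero variance)."""


def _masked_pairs(pred, target, mask) -> tuple[np.ndarray, np.ndarray]:
    pred, target, mask = (np.asarray(a, dtype=float) for a in (pred, target, mask))
    m = mask > 0
    if not m.any():
        raise UndefinedMetricError("no masked-in observations")
    return pred[m], target[m]


def rmse(pred, target, mask) -> float:
    """Root mean squared error over masked-in pairs (μg/mL)."""
    p, t = _masked_pairs(pred, target, mask)
    return float(np.sqrt(np.mean((p - t) ** 2)))


def mae(pred, target, mask) -> float:
    """Mean absolute error over masked-in pairs (μg/mL)."""
    p, t = _masked_pairs(pred, target, mask)
    return float(np.mean(np.abs(p - t)))


def r_squared(pred, target, mask) -> float:
    """Coefficient of determination 1 − SSE/SST over masked-in pairs.

    Negative when predictions explain less variance than the target mean.
    """
    p, t = _masked_pairs(pred, target, mask)
    if p.size < 2:
        raise UndefinedMetricError("need at least 2 observations")
    sst = float(np.sum((t - t.mean()) ** 2))
    if sst == 0:
        raise UndefinedMetricError("target variance is zero")
    return 1.0 - float(np.sum((t - p) ** 2)) / sst


def paired_t_mae(abs_errors_a, abs_errors_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-observation absolute errors.

    Returns (t statistic, p-value); positive t means model A's errors are
    larger.  Undefined for n < 2 or zero variance of the differences.
    """
    a = np.asarray(abs_errors_a, dtype=float)
    b = np.asarray(abs_errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired error vectors must have equal length")
    if a.size < 2:
        raise UndefinedMetricError("need at least 2 paired observations")
    if np.var(a - b) == 0:
        raise UndefinedMetricError("zero variance of paired differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EvalReport:
    """Masked metrics plus regression/classification agreement."""

    rmse: float
    r2: float
    mae: float
    n: int
    agreement_rate: float | None = None
    confusion: list[list[int]] | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def agreement_report(
    records: list[PredictionRecord],
    true_troughs: list[float] | None = None,
) -> tuple[float, np.ndarray | None]:
    """Consensus rate and (optionally) the 3×3 classifier-vs-truth confusion.

    The consensus rate is the fraction of records whose regression-implied
    range equals the classifier's ordinal range.  When true troughs are
    supplied (aligned with ``records``), the confusion matrix counts
    classifier class (rows) against true class (columns).
    """
    if not records:
        raise ValueError("empty prediction list")
    rate = float(np.mean([r.consensus for r in records]))
    confusion = None
    if true_troughs is not None:
        if len(true_troughs) != len(records):
            raise ValueError("true troughs must align with records")
        confusion = np.zeros((3, 3), dtype=int)
        for r, t in zip(records, true_troughs):
            confusion[CLASS_NAMES.index(r.class_pred), trough_class(t)] += 1
    return rate, confusion


def evaluate_predictions(pred, target, mask, records=None, true_troughs=None) -> EvalReport:
    """Bundle RMSE / R² / MAE (and agreement when records are given)."""
    p, t = _masked_pairs(pred, target, mask)
    report = EvalReport(
        rmse=rmse(pred, target, mask),
        r2=r_squared(pred, target, mask),
        mae=mae(pred, target, mask),
        n=int(p.size),
    )
    if records:
        rate, confusion = agreement_report(records, true_troughs)
        report.agreement_rate = rate
        report.confusion = confusion.tolist() if confusion is not None else None
    return report
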