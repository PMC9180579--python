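"""Metrics and attention analysis.

Predicted 557-class distributions are scored two ways: globally, as the
mean squared error over all (record, class) cells, and per aggregate task
after collapsing each distribution into the six task frequencies (1 bp
insertion, 1 bp deletion, deletion, 1 bp/2 bp/overall frameshift).  Task
agreement is measured by a median-split AUC, Pearson correlation, and
Kendall tau-b.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .labels import LabelError, LabelSpace, tasks_from_distribution

__all__ = [
    "UndefinedMetricError",
    "MetricReport",
    "mse",
    "auc_median_split",
    "pearson",
    "kendall_tau",
    "task_matrix",
    "evaluate_tasks",
    "high_attention_regions",
]

TASK_NAMES = ("ins1", "del1", "deletion", "frameshift1", "frameshift2", "frameshift_overall")


class UndefinedMetricError(ValueError):
    """A metric's preconditions (variance, class balance, n) are not met."""


def mse(pred: Sequence, true: Sequence) -> float:
    """Mean squared error over all (record, class) cells."""
    P = np.asarray(pred, dtype=float)
    T = np.asarray(true, dtype=float)
    if P.shape != T.shape:
        raise LabelError(f"shape mismatch: {P.shape} vs {T.shape}")
    return float(np.mean((P - T) ** 2))


def auc_median_split(pred_task: Sequence[float], true_task: Sequence[float]) -> float:
    """AUC after binarizing the true task values at their median.

    Values strictly above the median are the positive class; ties at the
    median go to the negative class.  The prediction is the ranking score
    (Mann-Whitney AUC with tie correction).
    """
    y = np.asarray(true_task, dtype=float)
    s = np.asarray(pred_task, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise LabelError("pred and true task vectors must be equal-length 1-D")
    if len(y) < 4:
        raise UndefinedMetricError("median-split AUC needs at least 4 records")
    labels = y > np.median(y)
    if labels.all() or not labels.any():
        raise UndefinedMetricError("one class is empty after the median split")
    return float(roc_auc_score(labels, s))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise UndefinedMetricError("pearson needs at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedMetricError("pearson undefined for zero-variance input")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = float(stats.pearsonr(x, y).statistic)
    if np.isnan(r):
        raise UndefinedMetricError("pearson undefined (effectively constant input)")
    return r


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall tau-b (tie-corrected) rank correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise UndefinedMetricError("kendall tau needs at least 3 points")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.kendalltau(x, y, variant="b")
    if np.isnan(res.statistic):
        raise UndefinedMetricError("kendall tau undefined (constant input)")
    return float(res.statistic)


def task_matrix(distributions: Sequence, space: LabelSpace) -> pd.DataFrame:
    """Collapse an (n, 557) array of distributions into six task columns."""
    rows = [tasks_from_distribution(p, space) for p in np.asarray(distributions, float)]
    return pd.DataFrame(rows, columns=TASK_NAMES)


@dataclass
class MetricReport:
    """Global MSE plus per-task AUC / Pearson / Kendall tau tables."""

    mse: float
    auc: dict[str, float] = field(default_factory=dict)
    pearson: dict[str, float] = field(default_factory=dict)
    kendall_tau: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "auc": self.auc,
            "pearson": self.pearson,
            "kendall_tau": self.kendall_tau,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"auc": self.auc, "pearson": self.pearson, "kendall_tau": self.kendall_tau}
        )


def evaluate_tasks(model, records, space: LabelSpace) -> MetricReport:
    """Score a fitted predictor on records carrying true distributions.

    ``model`` may be an estimator with ``predict`` or a precomputed
    (n, 557) prediction array.  Metric preconditions propagate as
    :class:`UndefinedMetricError`.
    """
    truths = np.stack([np.asarray(r.distribution, float) for r in records])
    if hasattr(model, "predict"):
        preds = model.predict([r.sequence for r in records])
    else:
        preds = np.asarray(model, dtype=float)
    report = MetricReport(mse=mse(preds, truths))
    t_true = task_matrix(truths, space)
    t_pred = task_matrix(preds, space)
    for task in TASK_NAMES:
        report.auc[task] = auc_median_split(t_pred[task].values, t_true[task].values)
        report.pearson[task] = pearson(t_pred[task].values, t_true[task].values)
        report.kendall_tau[task] = kendall_tau(t_pred[task].values, t_true[task].values)
    return report


def high_attention_regions(
    profile: Sequence[float],
    threshold_rule: str | float | Callable[[np.ndarray], float] = "mean+sd",
) -> list[tuple[int, int]]:
    """Maximal runs of 1-based token positions with above-threshold attention.

    The default threshold is mean + 1 standard deviation of the profile;
    a float or a callable(profile) -> float may be supplied instead.
    """
    a = np.asarray(profile, dtype=float)
    if callable(threshold_rule):
        thr = float(threshold_rule(a))
    elif threshold_rule == "mean+sd":
        thr = float(a.mean() + a.std())
    else:
        thr = float(threshold_rule)
    above = a > thr
    regions: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i + 1
        elif not flag and start is not None:
            regions.append((start, i))
            start = None
    if start is not None:
        regions.append((start, len(a)))
    return regions
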