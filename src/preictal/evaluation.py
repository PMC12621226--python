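"""Classification metrics and cross-model comparison statistics.

The positive class throughout is *pre-ictal* (label 0): sensitivity is the
recall of pre-ictal windows, specificity the recall of inter-ictal windows.
Model comparisons over cross-validation folds use a Welch two-sample t-test
and a pooled-SD Cohen's d, ``|d| = |m_a - m_b| / sqrt((s_a^2 + s_b^2)/2)``
(the equal-group-size form), with the conventional 0.2 / 0.5 / 0.8
interpretation cuts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Band = Literal["negligible", "small", "medium", "large"]

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "ComparisonResult",
    "confusion_from_labels",
    "metrics",
    "cohens_d",
    "welch_t",
    "interpret_d",
    "compare_models",
    "summarize_trials",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with pre-ictal as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class MetricSet:
    """Accuracy / sensitivity / specificity; None marks an undefined ratio."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None


@dataclass(frozen=True)
class ComparisonResult:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_stat: float
    df: float
    p_value: float
    cohens_d: float
    band: Band


def confusion_from_labels(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """Build the confusion matrix from label arrays (0 = pre-ictal positive)."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have the same length")
    return ConfusionMatrix(
        tp=int(np.sum((yt == 0) & (yp == 0))),
        fn=int(np.sum((yt == 0) & (yp == 1))),
        tn=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 1) & (yp == 0))),
    )


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).

    A zero denominator yields ``None`` for that metric rather than a silent 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = (cm.tp + cm.tn) / cm.total
    sen = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    spe = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else None
    return MetricSet(accuracy=acc, sensitivity=sen, specificity=spe)


def cohens_d(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Absolute pooled-SD effect size |d| = |m_a - m_b| / sqrt((s_a^2+s_b^2)/2)."""
    diff = abs(mean_a - mean_b)
    pooled = math.sqrt((sd_a**2 + sd_b**2) / 2.0)
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        return math.inf
    return diff / pooled


def welch_t(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> tuple[float, float, float]:
    """Welch two-sample t from summary statistics.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least two observations per group")
    va = sd_a**2 / n_a
    vb = sd_b**2 / n_b
    se2 = va + vb
    if se2 == 0.0:
        return 0.0, float(n_a + n_b - 2), 1.0
    t = (mean_a - mean_b) / math.sqrt(se2)
    df = se2**2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def interpret_d(d: float) -> Band:
    """Band |d| at the 0.2/0.5/0.8 cuts; boundaries go to the higher band."""
    d = abs(d)
    if d < 0.2:
        return "negligible"
    if d < 0.5:
        return "small"
    if d < 0.8:
        return "medium"
    return "large"


def compare_models(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> ComparisonResult:
    """Full paired-model comparison from fold-level summary statistics."""
    t, df, p = welch_t(mean_a, sd_a, n_a, mean_b, sd_b, n_b)
    d = cohens_d(mean_a, sd_a, mean_b, sd_b)
    return ComparisonResult(
        mean_a=mean_a, sd_a=sd_a, n_a=n_a,
        mean_b=mean_b, sd_b=sd_b, n_b=n_b,
        t_stat=t, df=df, p_value=p,
        cohens_d=d, band=interpret_d(d),
    )


def _round_half_up(x: float, ndigits: int) -> float:
    scale = 10**ndigits
    return math.floor(x * scale + 0.5) / scale


def summarize_trials(
    table: pd.DataFrame,
    precision: Mapping[str, int] | None = None,
) -> pd.Series:
    """Column means of a per-subject/per-trial hyperparameter table.

    ``precision`` maps column name -> decimal places for half-up rounding
    (0 means round to integer, reported as int). Columns absent from the
    map are returned unrounded.
    """
    means = table.mean(numeric_only=True)
    if precision:
        for col, ndp in precision.items():
            if col in means.index:
                val = _round_half_up(float(means[col]), ndp)
                means[col] = int(val) if ndp == 0 else val
    return means
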