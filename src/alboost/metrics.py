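"""Confusion-matrix statistics for two-class compound prediction.

Beyond accuracy, class-imbalance-robust statistics are reported: the
corrected classification rate CCR (balanced accuracy, the mean of
sensitivity and specificity), its complement the CCR error, the Matthews
correlation coefficient, and the sensitivity/specificity variance — half
the summed squared deviations of the two rates from their mean, on the
percent scale (units %^2) — which measures how biased a model is toward
one class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "compute_report"]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        """Number of truly positive (active) compounds."""
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        """Number of truly negative (inactive) compounds."""
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    ccr: float
    ccr_error: float
    accuracy: float
    mcc: float
    variance: float       # percent-squared scale
    mu: float             # mean of sensitivity and specificity, percent scale


def confusion(
    truth: Sequence, predicted: Sequence, positive_class, classes: Sequence | None = None
) -> ConfusionCounts:
    """2x2 cross-tabulation of true versus predicted labels."""
    t = np.asarray(truth, dtype=object)
    p = np.asarray(predicted, dtype=object)
    if t.size == 0:
        raise ValueError("empty label sequences")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.size} truths, {p.size} predictions")
    if classes is not None:
        bad = sorted((set(t) | set(p)) - set(classes))
        if bad:
            raise ValueError(f"labels outside declared classes {tuple(classes)}: {bad}")
    t_pos = t == positive_class
    p_pos = p == positive_class
    return ConfusionCounts(
        tp=int(np.sum(t_pos & p_pos)),
        tn=int(np.sum(~t_pos & ~p_pos)),
        fp=int(np.sum(~t_pos & p_pos)),
        fn=int(np.sum(t_pos & ~p_pos)),
    )


def compute_report(counts: ConfusionCounts) -> MetricsReport:
    """All prediction statistics from one confusion matrix.

    MCC is defined as 0 when any factor of its denominator vanishes
    (constant truth or constant prediction carries no correlation).
    """
    if counts.n_pos == 0 or counts.n_neg == 0:
        raise ValueError("both classes must be present in the evaluated set")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn

    sensitivity = tp / counts.n_pos
    specificity = tn / counts.n_neg
    ccr = (sensitivity + specificity) / 2
    accuracy = (tp + tn) / counts.total

    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tn * tp - fn * fp) / np.sqrt(denom_sq) if denom_sq > 0 else 0.0

    sens_pct, spec_pct = 100 * sensitivity, 100 * specificity
    mu = (sens_pct + spec_pct) / 2
    variance = 0.5 * (sens_pct - mu) ** 2 + 0.5 * (spec_pct - mu) ** 2

    return MetricsReport(
        sensitivity=sensitivity,
        specificity=specificity,
        ccr=ccr,
        ccr_error=1.0 - ccr,
        accuracy=accuracy,
        mcc=float(mcc),
        variance=float(variance),
        mu=float(mu),
    )
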