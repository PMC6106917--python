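"""Classification metrics, reliability and portability statistics.

Screening performance is summarised with the pathological class as
positive:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

all expressed as percentages and conventionally printed at one decimal.
Reliability is the fraction of repeat-recording pairs whose overall
verdicts disagree; portability is the sample standard deviation of one
parameter measured by several devices on the same source audio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .errors import UndefinedMetricError

HEALTHY = "healthy"
PATHOLOGICAL = "pathological"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_pathological(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    """Accuracy, sensitivity and specificity as percentages in [0, 100]."""

    accuracy: float
    sensitivity: float
    specificity: float

    def rounded(self, decimals: int = 1) -> "Metrics":
        return Metrics(
            accuracy=round(self.accuracy, decimals),
            sensitivity=round(self.sensitivity, decimals),
            specificity=round(self.specificity, decimals),
        )


def confusion(predicted: Sequence[str], truth: Sequence[str]) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with pathological as the positive class."""
    if len(predicted) != len(truth):
        raise ValueError(f"length mismatch: {len(predicted)} predictions vs {len(truth)} labels")
    tp = tn = fp = fn = 0
    for p, t in zip(predicted, truth):
        if p not in (HEALTHY, PATHOLOGICAL) or t not in (HEALTHY, PATHOLOGICAL):
            raise ValueError(f"labels must be healthy/pathological, got ({p!r}, {t!r})")
        if t == PATHOLOGICAL:
            if p == PATHOLOGICAL:
                tp += 1
            else:
                fn += 1
        else:
            if p == HEALTHY:
                tn += 1
            else:
                fp += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics_from_confusion(c: ConfusionCounts) -> Metrics:
    """The three ratio metrics as percentages; raises
    :class:`UndefinedMetricError` naming any metric with an empty
    denominator."""
    if c.total == 0:
        raise UndefinedMetricError("accuracy")
    if c.n_pathological == 0:
        raise UndefinedMetricError("sensitivity")
    if c.n_healthy == 0:
        raise UndefinedMetricError("specificity")
    return Metrics(
        accuracy=100.0 * (c.tp + c.tn) / c.total,
        sensitivity=100.0 * c.tp / c.n_pathological,
        specificity=100.0 * c.tn / c.n_healthy,
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def confusion_from_rates(
    n_pathological: int,
    n_healthy: int,
    sensitivity: float,
    specificity: float,
) -> ConfusionCounts:
    """Reconstruct integer confusion counts from class sizes and rates.

    ``sensitivity`` and ``specificity`` are fractions in [0, 1];
    products are rounded half-up to the nearest integer. Useful for
    consistency-checking published (accuracy, sensitivity, specificity)
    triples against their class split.
    """
    if n_pathological <= 0 or n_healthy <= 0:
        raise ValueError("class sizes must be positive")
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    tp = _round_half_up(n_pathological * sensitivity)
    tn = _round_half_up(n_healthy * specificity)
    return ConfusionCounts(tp=tp, fn=n_pathological - tp, tn=tn, fp=n_healthy - tn)


def repeatability_rate(paired_verdicts: Sequence[Tuple[str, str]]) -> float:
    """Fraction of repeat-recording pairs whose overall verdicts differ."""
    if len(paired_verdicts) == 0:
        raise ValueError("need at least one pair")
    discordant = sum(1 for a, b in paired_verdicts if a != b)
    return discordant / len(paired_verdicts)


def device_dispersion(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1 divisor) of repeated measurements of
    one parameter across devices, in the parameter's own units."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least two measurements")
    return float(np.std(values, ddof=1))
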