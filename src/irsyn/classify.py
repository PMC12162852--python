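"""Threshold classification of the 1656.0/1623.5 misfolding ratio.

Two schemes are implemented:

* single threshold (1.093): ratio below → misfolding positive;
* traffic light (1.065 / 1.14): ratio < 1.065 → red (high misfolding,
  clear synucleinopathy), ratio > 1.14 → green (low misfolding), values in
  between — thresholds included — → yellow (intermediate, at-risk).

Confusion metrics compare the extreme classes only: yellow subjects are
excluded, red counts as test-positive and green as test-negative against
the clinical PD/MSA grouping.  Reported percentages are rounded half-up to
integers; raw fractions are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["Thresholds", "ConfusionTable", "DEFAULT_THRESHOLDS",
           "classify_single", "classify_traffic_light",
           "confusion_from_counts", "confusion_from_extremes", "round_half_up"]


@dataclass(frozen=True)
class Thresholds:
    """Ratio thresholds (dimensionless): lower < single < upper."""

    single: float = 1.093
    lower: float = 1.065
    upper: float = 1.14

    def __post_init__(self):
        if not self.lower < self.single < self.upper:
            raise ValueError("thresholds must satisfy lower < single < upper")


DEFAULT_THRESHOLDS = Thresholds()


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves away from zero upward."""
    import math

    return int(math.floor(x + 0.5))


def classify_single(ratio: float, threshold: float = DEFAULT_THRESHOLDS.single) -> str:
    """Single-threshold call: ``positive`` (misfolding) iff ratio < threshold.

    A ratio exactly at the threshold is negative (documented boundary rule).
    """
    if not ratio > 0:
        raise ValueError("ratio must be positive")
    return "positive" if ratio < threshold else "negative"


def classify_traffic_light(ratio: float,
                           thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """Traffic-light call: red below the lower threshold, green above the
    upper, yellow in the closed interval between them."""
    if not ratio > 0:
        raise ValueError("ratio must be positive")
    if ratio < thresholds.lower:
        return "red"
    if ratio > thresholds.upper:
        return "green"
    return "yellow"


@dataclass
class ConfusionTable:
    """Counts plus sensitivity/specificity in percent (rounded half-up for
    reporting; raw fractions kept)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fn == 0 or self.fp + self.tn == 0:
            raise ValueError("metrics undefined: a truth class is empty")

    @property
    def sensitivity_fraction(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity_fraction(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def sensitivity(self) -> int:
        """Sensitivity in percent, rounded half-up."""
        return round_half_up(100.0 * self.sensitivity_fraction)

    @property
    def specificity(self) -> int:
        """Specificity in percent, rounded half-up."""
        return round_half_up(100.0 * self.specificity_fraction)


def confusion_from_counts(tp: int, fn: int, fp: int, tn: int) -> ConfusionTable:
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn)


def confusion_from_extremes(records: Sequence) -> ConfusionTable:
    """Confusion table over the extreme traffic-light classes.

    ``records`` need ``label`` (red/yellow/green) and ``is_positive`` (true
    PD/MSA group).  Yellow subjects are excluded; red is the test-positive
    call, green the test-negative call.
    """
    tp = fn = fp = tn = 0
    for r in records:
        if r.label == "yellow" or r.label is None:
            continue
        if r.label not in ("red", "green"):
            raise ValueError(f"unknown label {r.label!r}")
        if r.is_positive:
            tp += r.label == "red"
            fn += r.label == "green"
        else:
            fp += r.label == "red"
            tn += r.label == "green"
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn)
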