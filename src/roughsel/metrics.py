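"""Clinical performance metrics on the risky-vs-healthy dichotomy.

The three risk groups collapse to a binary test: very risky (1) and risky
(2) count as positive (disease present), healthy (3) as negative.  From
the resulting 2×2 confusion table the five standard measures are
reported: accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP),
positive predictive value TP/(TP+FP), and negative predictive value
TN/(TN+FN), all as percentages.  A measure whose denominator is zero is
reported as ``None`` rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "report"]

POSITIVE_CLASSES = frozenset({1, 2})


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_test(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy_pct: float | None
    sensitivity_pct: float | None
    specificity_pct: float | None
    ppv_pct: float | None
    npv_pct: float | None

    def format_row(self) -> str:
        def fmt(v: float | None) -> str:
            return "undefined" if v is None else f"{v:.2f}"

        return "\t".join(
            fmt(v)
            for v in (
                self.accuracy_pct,
                self.sensitivity_pct,
                self.specificity_pct,
                self.ppv_pct,
                self.npv_pct,
            )
        )


def confusion(
    predicted: Sequence[int],
    actual: Sequence[int],
    positive_classes: frozenset[int] = POSITIVE_CLASSES,
) -> ConfusionCounts:
    """Dichotomize both class-code vectors and tally the 2×2 table."""
    if len(predicted) != len(actual):
        raise ValueError("predicted and actual must have equal length")
    tp = fp = tn = fn = 0
    for p, a in zip(predicted, actual):
        pos_pred = p in positive_classes
        pos_act = a in positive_classes
        if pos_pred and pos_act:
            tp += 1
        elif pos_pred:
            fp += 1
        elif pos_act:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio_pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def report(c: ConfusionCounts) -> MetricsReport:
    return MetricsReport(
        accuracy_pct=_ratio_pct(c.tp + c.tn, c.n_test),
        sensitivity_pct=_ratio_pct(c.tp, c.tp + c.fn),
        specificity_pct=_ratio_pct(c.tn, c.tn + c.fp),
        ppv_pct=_ratio_pct(c.tp, c.tp + c.fp),
        npv_pct=_ratio_pct(c.tn, c.tn + c.fn),
    )
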