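"""Screen-evaluation statistics: confusion counts, sensitivity, specificity
and the power metric PM = TPR / (TPR + FPR)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ScreenMetrics:
    sensitivity: float
    specificity: float
    power_metric: float
    tpr: float
    fpr: float

    def rounded(self, ndigits: int = 2) -> "ScreenMetrics":
        """Half-up rounding for comparison with printed values."""
        r = lambda v: round_half_up(v, ndigits)
        return ScreenMetrics(
            sensitivity=r(self.sensitivity),
            specificity=r(self.specificity),
            power_metric=r(self.power_metric),
            tpr=r(self.tpr),
            fpr=r(self.fpr),
        )


def round_half_up(value: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def confusion(
    predictions: Mapping[str, bool], truth: Mapping[str, bool]
) -> ConfusionCounts:
    """Exact confusion counts over a shared compound set."""
    pset, tset = set(predictions), set(truth)
    if pset != tset:
        diff = sorted(pset.symmetric_difference(tset))
        raise ValueError(f"prediction/truth compound sets differ: {diff}")
    tp = fp = tn = fn = 0
    for cid in predictions:
        p, t = bool(predictions[cid]), bool(truth[cid])
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(counts: ConfusionCounts) -> ScreenMetrics:
    """Sensitivity, specificity and power metric from confusion counts.

    PM is defined as 0 (with a warning) when TPR = FPR = 0, which signals a
    screen that selects nothing.
    """
    if counts.tp + counts.fn == 0:
        raise ValueError("no positives in truth: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise ValueError("no negatives in truth: specificity undefined")
    tpr = counts.tp / (counts.tp + counts.fn)
    fpr = counts.fp / (counts.fp + counts.tn)
    if tpr + fpr == 0:
        warnings.warn("TPR = FPR = 0: power metric defined as 0 (useless screen)")
        pm = 0.0
    else:
        pm = tpr / (tpr + fpr)
    return ScreenMetrics(
        sensitivity=tpr,
        specificity=counts.tn / (counts.tn + counts.fp),
        power_metric=pm,
        tpr=tpr,
        fpr=fpr,
    )


def metrics_report(counts: ConfusionCounts, ndigits: int = 2) -> dict:
    """JSON-ready metrics block for one screen stage."""
    m = metrics(counts)
    mr = m.rounded(ndigits)
    return {
        "counts": {"tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn},
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "power_metric": m.power_metric,
        "rounded": {
            "sensitivity": mr.sensitivity,
            "specificity": mr.specificity,
            "power_metric": mr.power_metric,
        },
    }
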