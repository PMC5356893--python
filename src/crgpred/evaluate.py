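"""Confusion metrics, ROC by decision-score offset, and survival comparison.

The positive class is recurrent throughout.  ROC curves are generated the
way the decision rule itself is swept: an additive modifier moves the
margin (non-recurrence minus recurrence score), and sensitivity/
specificity are evaluated at every modifier where some prediction flips.
Kaplan-Meier estimation and the log-rank test are delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .classify import ScorePair, predict
from .data_model import RECURRENT

__all__ = [
    "ConfusionCounts",
    "confusion_metrics",
    "ROCCurve",
    "roc_by_modifier",
    "KMCurve",
    "km_curve",
    "logrank_test",
    "SurvivalComparison",
    "compare_survival",
]


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_predictions(
        cls, predicted: Mapping[str, str], truth: Mapping[str, bool]
    ) -> "ConfusionCounts":
        tp = fn = fp = tn = 0
        for sid, label in predicted.items():
            pos = label == RECURRENT
            if truth[sid]:
                tp += pos
                fn += not pos
            else:
                fp += pos
                tn += not pos
        return cls(tp=tp, fn=fn, fp=fp, tn=tn)


def confusion_metrics(c: ConfusionCounts) -> dict[str, Optional[float]]:
    """Accuracy, sensitivity, specificity, PPV and NPV as fractions.

    A metric whose denominator is zero is reported as None (not
    available), never as zero.
    """
    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    return {
        "accuracy": ratio(c.tp + c.tn, c.total),
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
    }


@dataclass
class ROCCurve:
    """Operating points (modifier, FPR, TPR) sorted along the curve."""

    points: list[tuple[float, float, float]]
    auc: float


def roc_by_modifier(
    score_pairs: Sequence[ScorePair], truth: Mapping[str, bool]
) -> ROCCurve:
    """ROC from the modifier sweep over the decision margins.

    Every modifier at which a prediction changes (the negated margins) is
    evaluated, plus sentinels below and above all change points, so the
    curve always includes (0,0) and (1,1).  AUC by trapezoid.
    """
    labels = np.array([bool(truth[p.sample_id]) for p in score_pairs])
    if labels.all() or not labels.any():
        raise ValueError("need at least one sample of each class")
    margins = np.array([p.margin for p in score_pairs])
    change_points = np.unique(-margins)
    span = max(1.0, np.ptp(change_points))
    modifiers = np.concatenate((
        [change_points[0] - span], change_points, [change_points[-1] + span]
    ))
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    pts = []
    for m in modifiers:
        called = margins + m >= 0  # tie -> recurrent, as in predict()
        tpr = float(np.sum(called & labels)) / n_pos
        fpr = float(np.sum(called & ~labels)) / n_neg
        pts.append((float(m), fpr, tpr))
    pts.sort(key=lambda t: (t[1], t[2]))
    fpr = np.array([p[1] for p in pts])
    tpr = np.array([p[2] for p in pts])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(points=pts, auc=auc)


@dataclass
class KMCurve:
    """Product-limit survival step function: S(t) at each distinct time."""

    times: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times: Sequence[float], event_flags: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier estimate; censored subjects leave the risk set without
    a survival drop.  Event = biochemical recurrence."""
    times = np.asarray(times, float)
    events = np.asarray(event_flags, bool)
    if times.size == 0:
        raise ValueError("empty group")
    if np.any(times <= 0):
        raise ValueError("times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
    )


def logrank_test(
    times_a: Sequence[float], events_a: Sequence[bool],
    times_b: Sequence[float], events_b: Sequence[bool],
) -> dict[str, float]:
    """Two-group log-rank test (hypergeometric variance at each event
    time, 1-df chi-square, two-sided p)."""
    ta = np.asarray(times_a, float)
    tb = np.asarray(times_b, float)
    ea = np.asarray(events_a, bool)
    eb = np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (ea.any() or eb.any()):
        raise ValueError("log-rank test needs at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return {"chi_square": float(res.test_statistic), "p": float(res.p_value)}


@dataclass
class SurvivalComparison:
    curve_a: KMCurve
    curve_b: KMCurve
    chi_square: float
    p_value: float


def compare_survival(times_a, events_a, times_b, events_b) -> SurvivalComparison:
    """KM curves for both groups plus the log-rank comparison."""
    lr = logrank_test(times_a, events_a, times_b, events_b)
    return SurvivalComparison(
        curve_a=km_curve(times_a, events_a),
        curve_b=km_curve(times_b, events_b),
        chi_square=lr["chi_square"],
        p_value=lr["p"],
    )
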