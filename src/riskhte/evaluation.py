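"""Predictive-ability assessment of the risk models.

Threshold classification metrics with confidence intervals, the
cumulative/dynamic time-dependent AUC at a fixed horizon under censoring
(nearest-neighbour bivariate-survival estimator), and per-subgroup
calibration of mean predicted risk against the Kaplan–Meier observed event
rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from riskhte.survival import event_rate_at, km_estimate

__all__ = [
    "MetricCI",
    "ClassificationMetrics",
    "CalibrationRow",
    "threshold_metrics",
    "time_dependent_auc",
    "calibration_by_subgroup",
]


@dataclass
class MetricCI:
    value: float
    lo: float
    hi: float


@dataclass
class ClassificationMetrics:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: MetricCI
    sensitivity: MetricCI
    specificity: MetricCI
    ppv: MetricCI | None  # None when no positive predictions were made

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _proportion_ci(successes: int, m: int, alpha: float, method: str) -> MetricCI:
    p = successes / m
    lo, hi = proportion_confint(successes, m, alpha=alpha, method=method)
    return MetricCI(value=p, lo=float(lo), hi=float(hi))


def threshold_metrics(
    labels,
    scores,
    threshold: float = 0.5,
    alpha: float = 0.05,
    ci_method: str = "normal",
) -> ClassificationMetrics:
    """Confusion-matrix metrics for ``score >= threshold`` predictions.

    Each metric's CI uses its own denominator (n for accuracy, positives for
    sensitivity, and so on); ``ci_method`` is "normal" (p ± z·sqrt(p(1−p)/m),
    default) or "wilson".  PPV is returned as None — undefined rather than
    zero — when there are no positive predictions.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    n = labels.size
    metrics = ClassificationMetrics(
        threshold=threshold,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=_proportion_ci(tp + tn, n, alpha, ci_method),
        sensitivity=_proportion_ci(tp, tp + fn, alpha, ci_method),
        specificity=_proportion_ci(tn, tn + fp, alpha, ci_method),
        ppv=_proportion_ci(tp, tp + fp, alpha, ci_method) if tp + fp > 0 else None,
    )
    return metrics


def _nn_weighted_survival(times, events, order_pct, span):
    """Conditional survival curves S(t | marker ≈ m_i) via nearest-neighbour
    weighted Kaplan–Meier: subject j contributes to i's curve when their
    marker rank percentiles differ by less than ``span``."""
    n = times.size
    time_order = np.argsort(times, kind="stable")
    t_sorted = times[time_order]
    e_sorted = events[time_order]
    pct_sorted = order_pct[time_order]

    def curve_for(i):
        in_window = np.abs(pct_sorted - order_pct[i]) <= span
        tw = t_sorted[in_window]
        ew = e_sorted[in_window]
        # product-limit over the window's event times (tw already sorted)
        m = tw.size
        surv_times = tw[ew == 1]
        uniq, counts = np.unique(surv_times, return_counts=True)
        at_risk = m - np.searchsorted(tw, uniq, side="left")
        factors = 1.0 - counts / at_risk
        return uniq, np.cumprod(factors)

    return curve_for


def time_dependent_auc(times, events, scores, horizon: float = 5.0, span: float | None = None) -> float:
    """Cumulative/dynamic AUC at ``horizon`` under right censoring.

    Uses the nearest-neighbour bivariate-survival estimator: a weighted
    Kaplan–Meier survival at the horizon is computed conditional on each
    marker value over a symmetric rank window of half-width ``span`` (default
    0.25·n^(−0.20)), and sensitivity/specificity at every marker cutpoint are
    read off the smoothed conditional survival.  The AUC is the trapezoidal
    area under the resulting ROC curve.  Cases are events by the horizon
    (cumulative), controls are subjects event-free at the horizon (dynamic).

    Invariant under strictly monotone transforms of the scores; reduces to
    the Mann–Whitney concordance when there is no censoring before the
    horizon (up to smoothing error).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n = times.size
    if not (times.shape == events.shape == scores.shape):
        raise ValueError("times, events and scores must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if np.sum((events == 1) & (times <= horizon)) == 0:
        raise ValueError("no events observed before the horizon")
    if span is None:
        span = 0.25 * n ** (-0.20)

    order = np.argsort(scores, kind="stable")
    pct = np.empty(n)
    pct[order] = np.arange(n) / max(n - 1, 1)

    curve_for = _nn_weighted_survival(times, events, pct, span)
    s_at_horizon = np.empty(n)
    for i in range(n):
        uniq, surv = curve_for(i)
        idx = np.searchsorted(uniq, horizon, side="right") - 1
        s_at_horizon[i] = 1.0 if idx < 0 else surv[idx]

    # sweep cutpoints from high to low marker value
    s_sorted = s_at_horizon[order]  # ascending marker
    f_sorted = 1.0 - s_sorted
    total_s = s_sorted.sum()
    total_f = f_sorted.sum()
    if total_f <= 0 or total_s <= 0:
        return 1.0 if total_s <= 0 else 0.0
    # TP(c) / FP(c) for cut just below each sorted marker value, highest first
    tp = np.cumsum(f_sorted[::-1]) / total_f
    fp = np.cumsum(s_sorted[::-1]) / total_s
    tp = np.concatenate([[0.0], tp])
    fp = np.concatenate([[0.0], fp])
    # enforce monotonicity (smoothing can produce tiny inversions)
    tp = np.maximum.accumulate(tp)
    fp = np.maximum.accumulate(fp)
    return float(np.trapezoid(tp, fp))


@dataclass
class CalibrationRow:
    subgroup: int
    mean_predicted: float
    observed_rate: float
    observed_se: float
    n: int


def calibration_by_subgroup(
    assignment, scores, table: pd.DataFrame, horizon: float = 5.0
) -> list[CalibrationRow]:
    """Mean predicted risk vs KM observed event rate at the horizon, per subgroup."""
    groups = np.asarray(getattr(assignment, "groups", assignment), dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(groups) != len(table) or len(scores) != len(table):
        raise ValueError("assignment/scores must align with the table")
    rows = []
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"subgroup {g} is empty")
        curve = km_estimate(table.loc[mask, "time"], table.loc[mask, "event"])
        rate, var = event_rate_at(curve, horizon)
        rows.append(
            CalibrationRow(
                subgroup=int(g),
                mean_predicted=float(scores[mask].mean()),
                observed_rate=rate,
                observed_se=float(np.sqrt(var)),
                n=int(mask.sum()),
            )
        )
    return rows
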