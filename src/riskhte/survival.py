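"""Survival statistics for subgroup treatment-effect analysis.

Kaplan–Meier estimation with Greenwood variance, absolute risk reduction
(ARR) at a fixed horizon with normal-approximation confidence intervals,
number needed to treat, Cochran's Q across subgroups (absolute scale), and
the Cox proportional-hazards treatment-by-subgroup interaction Wald test
(relative scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

__all__ = [
    "KMCurve",
    "ARREstimate",
    "NNTEstimate",
    "HeterogeneityTest",
    "SubgroupHR",
    "km_estimate",
    "event_rate_at",
    "arr_with_ci",
    "nnt_from_arr",
    "cochran_q",
    "cox_interaction_test",
    "subgroup_results_table",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``times`` holds the distinct *event* times in ascending order; ``survival``
    and ``variance`` are the Kaplan–Meier estimate and its Greenwood variance
    evaluated just after each event time.  ``max_time`` is the largest observed
    time (event or censored), which bounds where the curve is defined.
    """

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray
    n: int
    max_time: float

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def variance_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.variance[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier estimate S(t) = prod(1 - d_i/n_i) with Greenwood variance.

    Parameters
    ----------
    times : array-like of float
        Follow-up times (> 0), years.
    events : array-like of {0, 1}
        1 if the event was observed at ``times``, 0 if censored.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one observation")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times <= 0) or not np.all(np.isfinite(times)):
        raise ValueError("times must be finite and > 0")

    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    n = times.size

    event_times = np.unique(t_sorted[e_sorted == 1])
    surv = np.empty(event_times.size)
    var = np.empty(event_times.size)
    n_risk = np.empty(event_times.size, dtype=int)
    n_events = np.empty(event_times.size, dtype=int)

    s = 1.0
    greenwood_sum = 0.0
    for i, t in enumerate(event_times):
        at_risk = int(np.sum(t_sorted >= t))
        d = int(np.sum((t_sorted == t) & (e_sorted == 1)))
        s *= 1.0 - d / at_risk
        if at_risk > d:
            greenwood_sum += d / (at_risk * (at_risk - d))
        else:  # S drops to 0; variance of the estimate is 0 by convention
            greenwood_sum = np.inf
        n_risk[i] = at_risk
        n_events[i] = d
        surv[i] = s
        var[i] = s * s * greenwood_sum if s > 0 else 0.0

    return KMCurve(
        times=event_times,
        survival=surv,
        variance=var,
        n_risk=n_risk,
        n_events=n_events,
        n=n,
        max_time=float(t_sorted[-1]),
    )


def event_rate_at(curve: KMCurve, t: float) -> tuple[float, float]:
    """Cumulative event rate 1 - S(t) and its Greenwood variance.

    Requesting a time beyond the last observed time returns the rate at the
    last time and emits a ``RuntimeWarning``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t > curve.max_time:
        warnings.warn(
            f"horizon {t} exceeds last observed time {curve.max_time}; "
            "returning the rate at the last observed time",
            RuntimeWarning,
            stacklevel=2,
        )
        t = curve.max_time
    return 1.0 - curve.survival_at(t), curve.variance_at(t)


@dataclass
class ARREstimate:
    """Absolute risk reduction (control rate − treated rate) at a horizon."""

    subgroup: int
    rate_control: float
    rate_treated: float
    arr: float
    se: float
    lo: float
    hi: float
    n_control: int
    n_treated: int
    alpha: float = 0.05


def arr_with_ci(
    control_curve: KMCurve,
    treated_curve: KMCurve,
    t: float,
    alpha: float = 0.05,
    subgroup: int = 0,
) -> ARREstimate:
    """ARR at horizon ``t`` from two KM curves, normal-approximation CI.

    arr = (1 - S_control(t)) - (1 - S_treated(t));
    se  = sqrt(greenwood_control + greenwood_treated);
    CI  = arr ± z_{1-alpha/2} * se.
    """
    rc, vc = event_rate_at(control_curve, t)
    rt, vt = event_rate_at(treated_curve, t)
    arr = rc - rt
    se = float(np.sqrt(vc + vt))
    z = stats.norm.ppf(1 - alpha / 2)
    return ARREstimate(
        subgroup=subgroup,
        rate_control=rc,
        rate_treated=rt,
        arr=arr,
        se=se,
        lo=arr - z * se,
        hi=arr + z * se,
        n_control=control_curve.n,
        n_treated=treated_curve.n,
        alpha=alpha,
    )


@dataclass
class NNTEstimate:
    nnt: float
    lo: float
    hi: float
    ci_defined: bool


def nnt_from_arr(estimate: ARREstimate) -> NNTEstimate:
    """Number needed to treat, 1/ARR.

    The CI bounds are the order-swapped reciprocals of the ARR CI and are
    reported only when the ARR CI excludes zero; otherwise they are non-finite
    (an interval through ±infinity would be misleading).
    """
    if estimate.arr == 0:
        raise ValueError("NNT undefined for ARR = 0")
    nnt = 1.0 / estimate.arr
    if estimate.lo > 0 or estimate.hi < 0:
        return NNTEstimate(nnt=nnt, lo=1.0 / estimate.hi, hi=1.0 / estimate.lo, ci_defined=True)
    return NNTEstimate(nnt=nnt, lo=np.nan, hi=np.nan, ci_defined=False)


@dataclass
class HeterogeneityTest:
    scale: str  # "absolute" or "relative"
    statistic: float
    df: int
    p_value: float


def cochran_q(estimates: list[ARREstimate]) -> HeterogeneityTest:
    """Cochran's Q across subgroup ARRs (fixed-effect inverse-variance weights).

    Q = sum_g w_g (arr_g - pooled)^2 with w_g = 1/se_g^2 and
    pooled = sum w_g arr_g / sum w_g, compared to chi-squared with G-1 df.
    """
    if len(estimates) < 2:
        raise ValueError("Cochran's Q requires at least two subgroups")
    arr = np.array([e.arr for e in estimates])
    se = np.array([e.se for e in estimates])
    if np.any(se <= 0):
        raise ValueError("every subgroup ARR must have a positive standard error")
    w = 1.0 / se**2
    pooled = float(np.sum(w * arr) / np.sum(w))
    q = float(np.sum(w * (arr - pooled) ** 2))
    df = len(estimates) - 1
    return HeterogeneityTest(
        scale="absolute", statistic=q, df=df, p_value=float(stats.chi2.sf(q, df))
    )


@dataclass
class SubgroupHR:
    subgroup: int
    hr: float
    lo: float
    hi: float


def _check_subgroups(df: pd.DataFrame, on_sparse: str) -> pd.DataFrame:
    """Validate arm/event composition per subgroup; merge or fail on sparse ones."""
    while True:
        bad = None
        for g, sub in df.groupby("subgroup"):
            if sub["arm01"].nunique() < 2 or sub["event"].sum() < 1:
                bad = g
                break
        if bad is None:
            return df
        if on_sparse == "fail":
            raise ValueError(
                f"subgroup {bad} lacks both arms or has no events; "
                "merge groups or pass on_sparse='merge'"
            )
        groups = sorted(df["subgroup"].unique())
        if len(groups) < 2:
            raise ValueError("cannot merge: only one subgroup remains")
        i = groups.index(bad)
        target = groups[i - 1] if i > 0 else groups[1]
        df = df.copy()
        df.loc[df["subgroup"] == bad, "subgroup"] = target


def cox_interaction_test(
    table: pd.DataFrame,
    groups,
    alpha: float = 0.05,
    on_sparse: str = "fail",
    subgroup_hrs: bool = True,
) -> tuple[HeterogeneityTest, list[SubgroupHR]]:
    """Relative-scale heterogeneity: Wald test on treatment-by-subgroup interaction.

    Fits a Cox proportional-hazards model (Efron tie handling) with treatment
    arm, subgroup indicators, and their interaction, and returns the joint Wald
    chi-squared on the G-1 interaction coefficients, plus per-subgroup hazard
    ratios for treatment (each from a Cox fit within that subgroup).

    Parameters
    ----------
    table : DataFrame with columns ``arm`` ("treated"/"control"), ``event``,
        ``time``.
    groups : array of subgroup indices (1..G) aligned with ``table`` rows, or a
        ``SubgroupAssignment``.
    on_sparse : "fail" (default) raises when a subgroup misses an arm or has no
        events; "merge" collapses such a subgroup into its lower neighbour.
    """
    group_idx = np.asarray(getattr(groups, "groups", groups), dtype=int)
    if group_idx.shape[0] != len(table):
        raise ValueError("subgroup assignment does not align with the table")
    df = pd.DataFrame(
        {
            "time": np.asarray(table["time"], dtype=float),
            "event": np.asarray(table["event"], dtype=int),
            "arm01": (np.asarray(table["arm"]) == "treated").astype(int),
            "subgroup": group_idx,
        }
    )
    df = _check_subgroups(df, on_sparse)
    labels = sorted(df["subgroup"].unique())
    n_groups = len(labels)
    if n_groups < 2:
        raise ValueError("interaction test requires at least two subgroups")

    design = pd.DataFrame({"time": df["time"], "event": df["event"], "arm01": df["arm01"]})
    inter_cols = []
    for g in labels[1:]:
        ind = (df["subgroup"] == g).astype(int).to_numpy()
        design[f"g{g}"] = ind
        design[f"arm_x_g{g}"] = ind * df["arm01"].to_numpy()
        inter_cols.append(f"arm_x_g{g}")

    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox interaction model failed to converge: {exc}") from exc

    beta = cph.params_[inter_cols].to_numpy()
    cov = cph.variance_matrix_.loc[inter_cols, inter_cols].to_numpy()
    wald = float(beta @ np.linalg.solve(cov, beta))
    df_test = n_groups - 1
    test = HeterogeneityTest(
        scale="relative", statistic=wald, df=df_test, p_value=float(stats.chi2.sf(wald, df_test))
    )

    z = stats.norm.ppf(1 - alpha / 2)
    hrs = []
    if not subgroup_hrs:
        return test, hrs
    for g in labels:
        sub = design[df["subgroup"].to_numpy() == g]
        sub_fit = CoxPHFitter()
        sub_fit.fit(sub[["time", "event", "arm01"]], duration_col="time", event_col="event")
        b = float(sub_fit.params_["arm01"])
        s = float(sub_fit.standard_errors_["arm01"])
        with np.errstate(over="ignore"):  # separation in a sparse subgroup -> infinite bound
            hrs.append(
                SubgroupHR(subgroup=int(g), hr=np.exp(b), lo=np.exp(b - z * s), hi=np.exp(b + z * s))
            )
    return test, hrs


def subgroup_results_table(
    arrs: list[ARREstimate], hrs: list[SubgroupHR] | None = None
) -> pd.DataFrame:
    """Machine-readable per-subgroup summary (rates, ARR with CI, HR with CI)."""
    rows = []
    hr_by_group = {h.subgroup: h for h in (hrs or [])}
    for e in arrs:
        h = hr_by_group.get(e.subgroup)
        rows.append(
            {
                "subgroup": e.subgroup,
                "n_treated": e.n_treated,
                "n_control": e.n_control,
                "rate_treated": e.rate_treated,
                "rate_control": e.rate_control,
                "arr": e.arr,
                "arr_lo": e.lo,
                "arr_hi": e.hi,
                "hr": h.hr if h else np.nan,
                "hr_lo": h.lo if h else np.nan,
                "hr_hi": h.hi if h else np.nan,
            }
        )
    return pd.DataFrame(rows)
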