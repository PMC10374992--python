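"""Subtype-specific prognosis: cumulative mortality and competing-risks incidence.

All-cause mortality is one minus the Kaplan-Meier survival estimate with
pointwise 95% intervals on the log(-log S) scale (exponential Greenwood), via
lifelines.  The cumulative incidence of subsequent stroke treats death as a
competing risk and uses the Aalen-Johansen estimator

    F_k(t) = sum_{t_i <= t} S(t_i-) d_ki / n_i,

where S is the all-events Kaplan-Meier; its variance follows the standard
delta-method (Marubini-Valsecchi) formula and the interval is built on the
log F_k scale so bounds stay within [0, 1].  At tied times events are
processed before censorings; horizon readouts use the right-continuous step
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .config import EVENT_CENSORED, EVENT_DEATH, EVENT_STROKE

Z95 = 1.959963984540054


class RateReadout(NamedTuple):
    estimate: float
    lower: float
    upper: float
    flagged: bool = False


@dataclass
class SurvivalCurve:
    """Product-limit estimate over the distinct observed times."""

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    lower: np.ndarray  # 95% bounds on the survival scale
    upper: np.ndarray
    exhausted: bool = False  # risk set ran out before the last time

    @property
    def cumulative(self) -> np.ndarray:
        return 1.0 - self.survival

    def rate_at(self, horizon: float) -> RateReadout:
        """(1 - S, CI) at the last step <= horizon; flagged zero before the first time."""
        return _step_readout(self.times, 1.0 - self.survival,
                             1.0 - self.upper, 1.0 - self.lower, horizon)


@dataclass
class CIFEstimate:
    """Aalen-Johansen cumulative incidence for one cause."""

    times: np.ndarray  # distinct event times (any cause)
    at_risk: np.ndarray
    events_cause: np.ndarray
    events_all: np.ndarray
    cif: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    survival_all: np.ndarray  # all-events KM at the same grid
    cause: str = ""

    def rate_at(self, horizon: float) -> RateReadout:
        return _step_readout(self.times, self.cif, self.lower, self.upper, horizon)


def _step_readout(times, est, lo, hi, horizon) -> RateReadout:
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    idx = np.searchsorted(times, horizon, side="right") - 1
    if idx < 0:
        return RateReadout(0.0, 0.0, 0.0, flagged=True)
    return RateReadout(float(est[idx]), float(lo[idx]), float(hi[idx]), False)


def km_estimate(times, event_flags, alpha: float = 0.05) -> SurvivalCurve:
    """Kaplan-Meier with exponential Greenwood 95% intervals.

    ``event_flags`` is boolean (True = event, False = right-censored).
    """
    times = np.asarray(times, dtype=float)
    flags = np.asarray(event_flags, dtype=bool)
    if times.size == 0:
        raise ValueError("no observations")
    if np.any(times <= 0) or np.any(~np.isfinite(times)):
        raise ValueError("all times must be positive and finite")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, event_observed=flags)
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    grid = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[grid, "KM_estimate"].to_numpy()
    ci = kmf.confidence_interval_survival_function_.loc[grid]
    exhausted = bool(surv[-1] == 0.0)  # risk set ran out; curve is truncated there
    return SurvivalCurve(
        times=grid,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        survival=surv,
        lower=ci.iloc[:, 0].to_numpy(),
        upper=ci.iloc[:, 1].to_numpy(),
        exhausted=exhausted,
    )


_EVENT_CODES = (EVENT_STROKE, EVENT_DEATH, EVENT_CENSORED)


def cif_estimate(times, event_types, cause: str = EVENT_STROKE, alpha: float = 0.05) -> CIFEstimate:
    """Aalen-Johansen cumulative incidence of ``cause`` with competing events.

    ``event_types`` holds one of ``subsequent_stroke``, ``death`` or
    ``censored`` per subject.  The complement identity
    sum_k F_k(t) = 1 - S_all(t) holds exactly at every event time.
    """
    times = np.asarray(times, dtype=float)
    types = np.asarray(event_types, dtype=object)
    if times.size == 0:
        raise ValueError("no observations")
    if np.any(times <= 0) or np.any(~np.isfinite(times)):
        raise ValueError("all times must be positive and finite")
    bad = ~np.isin(types, _EVENT_CODES)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"unknown event code {types[row]!r} at row {row}")
    if cause not in (EVENT_STROKE, EVENT_DEATH):
        raise ValueError(f"unknown cause {cause!r}")

    n = times.size
    order = np.argsort(times, kind="stable")
    t_sorted, y_sorted = times[order], types[order]
    event_mask = y_sorted != EVENT_CENSORED
    grid = np.unique(t_sorted[event_mask])
    # counts at each grid time: events before censorings at ties
    left = np.searchsorted(t_sorted, grid, side="left")
    right = np.searchsorted(t_sorted, grid, side="right")
    at_risk = n - left
    cum_events = np.concatenate([[0], np.cumsum(event_mask)])
    cum_cause = np.concatenate([[0], np.cumsum(y_sorted == cause)])
    d_all = cum_events[right] - cum_events[left]
    d_cause = cum_cause[right] - cum_cause[left]

    frac = d_all / at_risk
    surv_all = np.cumprod(1.0 - frac)
    surv_before = np.concatenate([[1.0], surv_all[:-1]])  # S(t-)
    jumps = surv_before * d_cause / at_risk
    cif = np.cumsum(jumps)

    # delta-method variance (Marubini & Valsecchi), then CI on the log scale
    with np.errstate(divide="ignore", invalid="ignore"):
        a = d_all / (at_risk * (at_risk - d_all))  # Greenwood increments
    a[~np.isfinite(a)] = 0.0
    b = surv_before**2 * (at_risk - d_cause) * d_cause / at_risk**3
    c = surv_before * d_cause / at_risk**2
    # expand sum_i (F_j - F_i)^2 a_i etc. into cumulative sums for O(m) evaluation
    A, FA, FFA = np.cumsum(a), np.cumsum(cif * a), np.cumsum(cif**2 * a)
    B, C, FC = np.cumsum(b), np.cumsum(c), np.cumsum(cif * c)
    var = cif**2 * A - 2.0 * cif * FA + FFA + B - 2.0 * (cif * C - FC)
    var = np.maximum(var, 0.0)
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_se = np.where(cif > 0, se / cif, 0.0)
    lower = np.where(cif > 0, cif * np.exp(-Z95 * log_se), 0.0)
    upper = np.where(cif > 0, np.minimum(cif * np.exp(Z95 * log_se), 1.0), 0.0)
    return CIFEstimate(
        times=grid, at_risk=at_risk.astype(int), events_cause=d_cause.astype(int),
        events_all=d_all.astype(int), cif=cif, lower=lower, upper=upper,
        survival_all=surv_all, cause=cause,
    )


def rate_at(curve, horizon: float) -> RateReadout:
    """Step-function readout (estimate, lower, upper) at the horizon."""
    return curve.rate_at(horizon)


# ---- sklearn-style estimator wrappers ----------------------------------

class KaplanMeierEstimator:
    """fit(durations, event_observed) -> curve_; rate readouts via rate_at."""

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def get_params(self, deep=True):
        return {"alpha": self.alpha}

    def set_params(self, **p):
        for k, v in p.items():
            setattr(self, k, v)
        return self

    def fit(self, durations, event_observed) -> "KaplanMeierEstimator":
        self.curve_ = km_estimate(durations, event_observed, alpha=self.alpha)
        return self

    def rate_at(self, horizon: float) -> RateReadout:
        return self.curve_.rate_at(horizon)


class AalenJohansenEstimator:
    """fit(durations, event_types) -> curve_ for the configured cause."""

    def __init__(self, cause: str = EVENT_STROKE, alpha: float = 0.05):
        self.cause = cause
        self.alpha = alpha

    def get_params(self, deep=True):
        return {"cause": self.cause, "alpha": self.alpha}

    def set_params(self, **p):
        for k, v in p.items():
            setattr(self, k, v)
        return self

    def fit(self, durations, event_types) -> "AalenJohansenEstimator":
        self.curve_ = cif_estimate(durations, event_types, cause=self.cause, alpha=self.alpha)
        return self

    def rate_at(self, horizon: float) -> RateReadout:
        return self.curve_.rate_at(horizon)


# ---- cohort-level analyses ---------------------------------------------

def stroke_analysis_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """First-event view for the subsequent-stroke analysis (death competing)."""
    return pd.DataFrame({"time": cohort["time"], "event": cohort["event"]})


def mortality_analysis_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Death follow-up: a non-fatal subsequent stroke does not end follow-up."""
    t = np.minimum(cohort["t_death"], cohort["t_censor"]).to_numpy()
    died = (cohort["t_death"] <= cohort["t_censor"]).to_numpy()
    return pd.DataFrame({"time": t, "died": died})


def compare_groups(cohort: pd.DataFrame, groups, horizon: float = 5.0,
                   min_group_size: int = 10) -> pd.DataFrame:
    """5-year subsequent-stroke CIF and all-cause mortality (1-KM) per group.

    ``groups`` is a label per cohort row; rows with null labels are excluded.
    Groups smaller than ``min_group_size`` are reported with a small-sample flag.
    """
    groups = pd.Series(np.asarray(groups, dtype=object), index=cohort.index)
    rows = []
    for name in sorted(groups.dropna().unique(), key=str):
        sub = cohort[groups == name]
        if len(sub) < min_group_size:
            warnings.warn(f"group {name!r} has fewer than {min_group_size} cases")
        stroke = cif_estimate(sub["time"], sub["event"], cause=EVENT_STROKE)
        s5 = stroke.rate_at(horizon)
        mort_frame = mortality_analysis_frame(sub)
        mort = km_estimate(mort_frame["time"], mort_frame["died"])
        m5 = mort.rate_at(horizon)
        rows.append({
            "group": name, "n": int(len(sub)),
            "stroke_rate": s5.estimate, "stroke_lower": s5.lower, "stroke_upper": s5.upper,
            "mortality": m5.estimate, "mortality_lower": m5.lower, "mortality_upper": m5.upper,
            "small_sample": len(sub) < min_group_size,
        })
    return pd.DataFrame(rows)


def curve_to_frame(curve) -> pd.DataFrame:
    """CSV-ready view: time, at_risk, events, estimate, lower, upper."""
    if isinstance(curve, SurvivalCurve):
        return pd.DataFrame({
            "time": curve.times, "at_risk": curve.at_risk, "events": curve.events,
            "estimate": curve.cumulative, "lower": 1.0 - curve.upper, "upper": 1.0 - curve.lower,
        })
    return pd.DataFrame({
        "time": curve.times, "at_risk": curve.at_risk, "events": curve.events_cause,
        "estimate": curve.cif, "lower": curve.lower, "upper": curve.upper,
    })
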