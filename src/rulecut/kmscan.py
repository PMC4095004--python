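"""Kaplan-Meier estimation, log-rank comparison and the expression-cutoff scan.

The scan is the univariate survival-based cross-check for supervised
cutoffs: for one probe set it evaluates every candidate cutoff (slot
midpoints between adjacent distinct expression values), splits the cohort
into low/high expression groups, and keeps the cutoff maximizing the
log-rank statistic between the two survival curves, together with which
expression side ("high" or "low") has the inferior curve.  A minimum group
size guards against degenerate extreme cutoffs.  No multiplicity
correction is applied to the scanned p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .dataset import ExpressionDataset
from .discretize import CutoffSet

__all__ = ["km_curve", "logrank_stat", "scan_best_cutoff", "ScanResult",
           "compare_with_cutoffs"]


def km_curve(times, events=None) -> pd.Series:
    """Product-limit survival estimate as a right-continuous step function.

    Returns a Series of survival probabilities indexed by time, starting
    at S(0) = 1.  ``events`` defaults to all-observed (no censoring).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("needs at least one sample")
    if (times < 0).any():
        raise ValueError("negative survival time")
    events = np.ones_like(times) if events is None else np.asarray(events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    s = kmf.survival_function_.iloc[:, 0]
    s.name = "survival"
    return s


def logrank_stat(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """One-degree-of-freedom log-rank (chi-square statistic, p-value)."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = logrank_test(times_a, times_b, event_observed_A=events_a,
                       event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def _logrank_grid(expression: np.ndarray, times: np.ndarray,
                  events: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-rank chi-square for every split of the expression-sorted cohort.

    Returns (cutoff midpoints, group-below sizes, chi-square statistics) for
    splits after each distinct expression value; computed with the standard
    tie-corrected hypergeometric variance, identical to the two-group
    log-rank test, but evaluated for all cutoffs at once via prefix sums
    along the expression order.
    """
    order = np.argsort(expression, kind="stable")
    ex = expression[order]
    t = times[order]
    e = np.asarray(events)[order].astype(float)
    ev_times = np.unique(t[e == 1])
    # risk and death indicator matrices, samples (expression order) x times
    at_risk = t[:, None] >= ev_times[None, :]
    death = (t[:, None] == ev_times[None, :]) & (e[:, None] == 1)
    n_t = at_risk.sum(axis=0)
    d_t = death.sum(axis=0)
    # prefix sums: row k = totals over the k smallest expression values
    n1 = np.cumsum(at_risk, axis=0)
    d1 = np.cumsum(death, axis=0)
    # candidate splits: after the last occurrence of each distinct value
    distinct_idx = np.flatnonzero(np.diff(ex) > 0)
    mids = (ex[distinct_idx] + ex[distinct_idx + 1]) / 2.0
    n1c = n1[distinct_idx]
    d1c = d1[distinct_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = n1c / n_t[None, :]
        o_minus_e = (d1c - d_t[None, :] * frac).sum(axis=1)
        var_terms = d_t[None, :] * frac * (1 - frac) \
            * (n_t - d_t)[None, :] / np.maximum(n_t - 1, 1)[None, :]
        var = np.where(n_t[None, :] > 1, var_terms, 0.0).sum(axis=1)
        stat = np.where(var > 0, o_minus_e ** 2 / var, 0.0)
    return mids, distinct_idx + 1, stat


@dataclass
class ScanResult:
    cutoff: float
    worse_direction: str  # expression side ("high"/"low") with inferior survival
    statistic: float
    p_value: float
    n_low: int
    n_high: int


def _worse_direction(times, events, high_mask) -> str:
    """Which expression group's KM curve is lower at the last event time."""
    times = np.asarray(times, float)
    events = np.asarray(events)
    t_ref = float(times[events == 1].max()) if (events == 1).any() \
        else float(times.max())
    surv = {}
    for name, mask in (("low", ~high_mask), ("high", high_mask)):
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        surv[name] = float(kmf.predict(t_ref))
    if surv["high"] < surv["low"]:
        return "high"
    if surv["low"] < surv["high"]:
        return "low"
    # equal at the horizon: compare restricted means, default to "high"
    means = {}
    grid = np.unique(times[times <= t_ref])
    for name, mask in (("low", ~high_mask), ("high", high_mask)):
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        means[name] = float(np.mean(kmf.predict(grid)))
    return "high" if means["high"] <= means["low"] else "low"


def scan_best_cutoff(expression, times, events,
                     min_group_size: int = 5) -> ScanResult:
    """Exhaustive cutoff scan maximizing the log-rank statistic.

    Candidate cutoffs are the midpoints between adjacent distinct
    expression values; only splits leaving both groups with at least
    ``min_group_size`` samples are eligible.  Ties go to the lower cutoff.
    """
    expression = np.asarray(expression, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if (times < 0).any():
        raise ValueError("negative survival time")
    if len(np.unique(expression)) < 2:
        raise ValueError("needs >= 2 distinct expression values")
    n = len(expression)
    mids, n_lows, stats = _logrank_grid(expression, times, events)
    eligible = np.minimum(n_lows, n - n_lows) >= min_group_size
    if not eligible.any():
        raise ValueError(
            f"no eligible cutoff with both groups >= {min_group_size}")
    idx = np.flatnonzero(eligible)
    best = idx[int(np.argmax(stats[idx]))]  # ties -> lower cutoff
    cutoff = float(mids[best])
    high = expression > cutoff
    stat, p = logrank_stat(times[~high], events[~high],
                           times[high], events[high])
    direction = _worse_direction(times, events, high)
    return ScanResult(cutoff, direction, stat, p,
                      int((~high).sum()), int(high.sum()))


def compare_with_cutoffs(dataset: ExpressionDataset, cutoffs: CutoffSet,
                         min_group_size: int = 5) -> pd.DataFrame:
    """Concordance harness: KM-scan cutoff vs supervised cutoff per feature.

    For every single-cutoff feature of ``cutoffs``, runs the scan on the
    dataset's survival columns and reports both cutoffs and the relative
    difference |KM - supervised| / supervised.  The table is reported, not
    asserted against any bound.
    """
    if dataset.survival_time is None:
        raise ValueError("dataset has no survival annotations")
    rows = []
    for feature, cl in cutoffs.cutoffs.items():
        if len(cl) != 1:
            continue
        sup = cl[0].value
        try:
            res = scan_best_cutoff(dataset.column(feature),
                                   dataset.survival_time,
                                   dataset.survival_event,
                                   min_group_size=min_group_size)
        except ValueError:
            continue
        rows.append({
            "feature": feature, "supervised_cutoff": sup,
            "km_cutoff": res.cutoff, "worse_direction": res.worse_direction,
            "statistic": res.statistic, "p_value": res.p_value,
            "relative_difference": abs(res.cutoff - sup) / abs(sup)
            if sup else np.inf,
        })
    return pd.DataFrame(rows)
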