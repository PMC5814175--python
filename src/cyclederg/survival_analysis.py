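"""Quartile stratification, Kaplan-Meier estimation, two-group log-rank test.

Patients are stratified by a single gene's expression into the top and
bottom quartiles (inclusive cuts at the 25th/75th percentiles; the middle
half is discarded), survival in each stratum is summarised by the
product-limit estimator, and the strata are compared with the standard
two-group log-rank chi-square test (1 df, two-sided p, no continuity
correction).

Estimation is delegated to lifelines (KaplanMeierFitter and the
statistics.logrank_test) behind this module's result types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .data_io import DataValidationError, SurvivalTable

__all__ = [
    "KMCurve",
    "LogRankResult",
    "stratify_quartiles",
    "km_estimate",
    "logrank_test",
]


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times.

    ``survival[i]`` is S(t) just after ``event_times[i]``; ``at_risk[i]``
    and ``events[i]`` are the risk-set size just before, and the number of
    deaths at, that time.  S = prod(1 - d_i/n_i) holds exactly at every
    step.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float
    observed: tuple[float, float]  # per-group event totals
    expected: tuple[float, float]


def stratify_quartiles(table: SurvivalTable) -> tuple[SurvivalTable, SurvivalTable]:
    """Split patients into high (>= 75th pct) and low (<= 25th pct) strata.

    Cuts are inclusive: a sample exactly at the percentile boundary joins
    the extreme group.  The middle half is discarded.  Raises when either
    group would be empty (degenerate covariate).
    """
    cov = table.covariates
    if np.isnan(cov).any():
        raise DataValidationError("every record needs a covariate value")
    if len(table) < 8:
        raise DataValidationError("need at least 8 records to stratify quartiles")
    q25, q75 = np.quantile(cov, [0.25, 0.75], method="linear")
    if q25 == q75:
        raise DataValidationError(
            "degenerate covariate: 25th and 75th percentiles coincide"
        )
    high_ids = [r.sample_id for r in table.records if r.covariate >= q75]
    low_ids = [r.sample_id for r in table.records if r.covariate <= q25]
    if not high_ids or not low_ids:
        raise DataValidationError("empty quartile stratum")
    return table.subset(high_ids), table.subset(low_ids)


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Censored observations reduce the risk set but add no step; at tied
    times, events are processed before censorings (the standard
    convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise DataValidationError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    has_event = tab["observed"] > 0
    ev_times = tab.index.values[has_event]
    d = tab["observed"].values[has_event].astype(float)
    n = tab["at_risk"].values[has_event].astype(float)
    surv = np.asarray(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in ev_times]
    )
    return KMCurve(
        event_times=np.asarray(ev_times, dtype=float),
        survival=surv,
        at_risk=n,
        events=d,
    )


def logrank_test(group_a: SurvivalTable, group_b: SurvivalTable) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct event time, expected events per group come from the
    hypergeometric mean and the variance from the hypergeometric variance;
    chi2 = (O-E)^2/V with a two-sided p from the chi-square(1) upper tail.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise DataValidationError("both groups must be non-empty")
    total_events = int(group_a.events.sum() + group_b.events.sum())
    if total_events == 0:
        raise DataValidationError("log-rank needs at least one event")
    res = _ll_logrank(
        group_a.times, group_b.times, group_a.events, group_b.events
    )
    obs, exp = _observed_expected(group_a, group_b)
    return LogRankResult(
        chi2=float(res.test_statistic),
        df=1,
        p=float(res.p_value),
        observed=obs,
        expected=exp,
    )


def _observed_expected(
    group_a: SurvivalTable, group_b: SurvivalTable
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Per-group observed and expected event totals across event times."""
    ta, ea = group_a.times, group_a.events
    tb, eb = group_b.times, group_b.events
    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    oa = float(ea.sum())
    ob = float(eb.sum())
    exp_a = 0.0
    for t in event_times:
        na = float((ta >= t).sum())
        nb = float((tb >= t).sum())
        da = float(((ta == t) & ea).sum())
        db = float(((tb == t) & eb).sum())
        n, d = na + nb, da + db
        if n > 0:
            exp_a += d * na / n
    exp_b = (oa + ob) - exp_a
    return (oa, ob), (exp_a, exp_b)
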