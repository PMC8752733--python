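"""Per-person wellbeing scores under four aggregation formulas.

For a person's Q reports of one method, with scores SWB_i and durations
Dur_i spread over D days:

* total SWB            — plain mean,  (1/Q) * sum_i SWB_i
* total weighted SWB   — duration-weighted mean,
                         sum_i Dur_i SWB_i / sum_i Dur_i
* daily SWB            — mean over days of the within-day mean, each day's
                         mean using that day's own report count Q_j
* daily weighted SWB   — mean over days of the within-day duration-weighted
                         mean

The difference between the weighted and unweighted total obeys an exact
covariance identity,

    total_weighted_swb - total_swb = cov(Dur, SWB) / mean(Dur)

with cov taken in the population (1/Q) convention.  Zero intensity-duration
covariance therefore forces a zero weighting difference — the mechanism by
which duration weighting can leave overall wellbeing unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .reportset import DRM, EMA, ReportSet

__all__ = [
    "total_swb",
    "total_weighted_swb",
    "daily_swb",
    "daily_weighted_swb",
    "summarize_persons",
    "summarize_cohort",
    "compare_method_durations",
    "UndefinedScoreError",
    "MEASURES",
]

MEASURES = ("happiness", "worthwhileness")


class UndefinedScoreError(ValueError):
    """The score is undefined (no reports, or zero total duration)."""


def _score_series(reports: pd.DataFrame, measure: str) -> pd.DataFrame:
    sub = reports.dropna(subset=[measure])
    if sub.empty:
        raise UndefinedScoreError(f"no reports with a {measure} score")
    return sub


def total_swb(reports: pd.DataFrame, measure: str = "happiness") -> float:
    """Arithmetic mean of the measure over all reports."""
    return float(_score_series(reports, measure)[measure].astype(float).mean())


def total_weighted_swb(reports: pd.DataFrame, measure: str = "happiness") -> float:
    """Duration-weighted mean of the measure over all reports."""
    sub = _score_series(reports, measure)
    w = sub["duration_min"].astype(float)
    if w.sum() <= 0:
        raise UndefinedScoreError("zero total duration")
    return float(np.average(sub[measure].astype(float), weights=w))


def daily_swb(reports: pd.DataFrame, measure: str = "happiness") -> float:
    """Mean over days of the within-day mean (days weighted equally)."""
    sub = _score_series(reports, measure)
    return float(sub.groupby("day_index")[measure].mean().mean())


def daily_weighted_swb(reports: pd.DataFrame, measure: str = "happiness") -> float:
    """Mean over days of the within-day duration-weighted mean."""
    sub = _score_series(reports, measure)
    daily = sub.groupby("day_index").apply(
        lambda g: np.average(g[measure].astype(float), weights=g["duration_min"].astype(float)),
        include_groups=False,
    )
    return float(daily.mean())


def summarize_persons(rs: ReportSet, measures=MEASURES) -> pd.DataFrame:
    """All four scores, and their weighted-unweighted differences, per cell.

    One row per person x method x measure with columns ``total_swb``,
    ``total_weighted_swb``, ``daily_swb``, ``daily_weighted_swb``,
    ``diff_total``, ``diff_daily``, ``q_reports``, ``d_days``.  Cells with no
    scored reports are omitted.
    """
    rows = []
    for (pid, method), g in rs.reports.groupby(["person_id", "method"], sort=False):
        for measure in measures:
            sub = g.dropna(subset=[measure])
            if sub.empty:
                continue
            t = total_swb(sub, measure)
            tw = total_weighted_swb(sub, measure)
            d = daily_swb(sub, measure)
            dw = daily_weighted_swb(sub, measure)
            rows.append(
                dict(
                    person_id=pid, method=method, measure=measure,
                    total_swb=t, total_weighted_swb=tw,
                    daily_swb=d, daily_weighted_swb=dw,
                    diff_total=tw - t, diff_daily=dw - d,
                    q_reports=len(sub), d_days=sub["day_index"].nunique(),
                )
            )
    return pd.DataFrame(rows)


def _mean_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    x = np.asarray(x, float)
    n = len(x)
    m = x.mean()
    if n < 2 or np.std(x) == 0:
        return (m, m)
    half = stats.t.ppf(0.5 + level / 2, n - 1) * x.std(ddof=1) / np.sqrt(n)
    return (m - half, m + half)


def summarize_cohort(rs: ReportSet, measures=MEASURES) -> pd.DataFrame:
    """Report-level descriptives per method and variable.

    Pooled mean, SD, median and t-based 95% CI of the intensity scores and of
    the durations, one row per method x variable.
    """
    rows = []
    df = rs.reports
    for method in (EMA, DRM):
        g = df[df["method"] == method]
        if g.empty:
            continue
        for measure in measures:
            x = g[measure].dropna().astype(float).to_numpy()
            if len(x) == 0:
                continue
            lo, hi = _mean_ci(x)
            rows.append(
                dict(method=method, variable=measure, n=len(x), mean=x.mean(),
                     median=float(np.median(x)), sd=x.std(ddof=1) if len(x) > 1 else 0.0,
                     ci_low=lo, ci_high=hi)
            )
        x = g["duration_min"].astype(float).to_numpy()
        lo, hi = _mean_ci(x)
        rows.append(
            dict(method=method, variable="duration_min", n=len(x), mean=x.mean(),
                 median=float(np.median(x)), sd=x.std(ddof=1) if len(x) > 1 else 0.0,
                 ci_low=lo, ci_high=hi)
        )
    return pd.DataFrame(rows)


def compare_method_durations(rs: ReportSet) -> dict:
    """Paired comparison of mean report duration, DRM minus EMA.

    Person mean durations per method are compared with a paired two-sided
    t-test; persons lacking either method are skipped (their ids are
    returned under ``skipped``).  Meaningful once EMA doubling is applied.
    """
    means = rs.reports.pivot_table(
        index="person_id", columns="method", values="duration_min", aggfunc="mean"
    ).reindex(columns=[EMA, DRM])
    complete = means.dropna()
    skipped = sorted(set(means.index) - set(complete.index))
    if len(complete) < 2:
        raise UndefinedScoreError("need >= 2 persons with both methods")
    diff = complete[DRM] - complete[EMA]
    if diff.std(ddof=1) == 0:
        t, p = (np.inf if diff.mean() != 0 else 0.0), (0.0 if diff.mean() != 0 else 1.0)
    else:
        t, p = stats.ttest_rel(complete[DRM], complete[EMA])
    return dict(
        mean_diff=float(diff.mean()), t=float(t), p=float(p),
        n_persons=len(complete), skipped=skipped,
    )
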