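"""Mechanism analyses: what drives a non-zero weighting difference?

By the covariance identity, the weighted-unweighted gap for a person is
r * sd(score) * sd(duration) / mean(duration); the three candidate drivers
are therefore the intensity-duration correlation and the two spreads.  This
module provides:

* per-person driver features (r, sd of intensity, sd of duration, the
  observed diffs);
* the max-correlation subsampling probe — draw many random half-subsets of
  a person's reports and keep the one with the highest |r|, deliberately
  inflating the correlation to see whether duration then starts to matter;
* a percentile curve of |diff| against the selected-subset |r|;
* an OLS drivers regression of the (absolute) weighting difference on the
  standardized features;
* the carryover (emotional-lag) regression of the current score on the
  previous episode's score and duration within person-day sequences.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .aggregate import total_swb, total_weighted_swb
from .reportset import ReportSet

__all__ = [
    "DriverFeatures",
    "person_driver_features",
    "driver_features_table",
    "max_correlation_subsample",
    "SubsampleResult",
    "correlation_percentile_curve",
    "drivers_regression",
    "carryover_regression",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    pass


@dataclasses.dataclass
class DriverFeatures:
    person_id: str
    method: str
    measure: str
    n: int
    r_intensity_duration: float  # NaN when undefined (zero variance / n < 3)
    sd_intensity: float
    sd_duration: float
    diff_total: float
    diff_daily: float


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def person_driver_features(reports: pd.DataFrame, measure: str = "happiness") -> DriverFeatures:
    """Sample SDs, Pearson r and the weighting diffs for one person's reports."""
    sub = reports.dropna(subset=[measure])
    if len(sub) < 3:
        raise InsufficientDataError("need >= 3 reports for stable driver features")
    s = sub[measure].astype(float).to_numpy()
    d = sub["duration_min"].astype(float).to_numpy()
    from .aggregate import daily_swb, daily_weighted_swb

    t, tw = total_swb(sub, measure), total_weighted_swb(sub, measure)
    dy, dyw = daily_swb(sub, measure), daily_weighted_swb(sub, measure)
    return DriverFeatures(
        person_id=str(sub["person_id"].iloc[0]),
        method=str(sub["method"].iloc[0]),
        measure=measure,
        n=len(sub),
        r_intensity_duration=_pearson(s, d),
        sd_intensity=float(np.std(s, ddof=1)),
        sd_duration=float(np.std(d, ddof=1)),
        diff_total=tw - t,
        diff_daily=dyw - dy,
    )


def driver_features_table(rs: ReportSet, measure: str = "happiness", method: str | None = None) -> pd.DataFrame:
    """Driver features for every person x method cell with >= 3 reports."""
    df = rs.reports
    if method is not None:
        df = df[df["method"] == method]
    rows = []
    for _, g in df.groupby(["person_id", "method"], sort=False):
        try:
            rows.append(dataclasses.asdict(person_driver_features(g, measure)))
        except InsufficientDataError:
            continue
    return pd.DataFrame(rows)


@dataclasses.dataclass
class SubsampleResult:
    indices: np.ndarray  # positional indices of the selected reports
    r: float  # Pearson r of the selected subset
    abs_r_percentile: float  # percentile of |r| among the candidate subsets
    candidate_r: np.ndarray


def max_correlation_subsample(
    reports: pd.DataFrame,
    measure: str = "happiness",
    n_sets: int = 100,
    fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
    signed: bool = False,
) -> SubsampleResult:
    """Pick, out of ``n_sets`` random half-subsets, the one maximizing |r|.

    Subsets are drawn without replacement (each report appears at most once
    per subset; subsets are independent of each other), of size
    ``floor(Q * fraction)``.  Ties are broken in favour of the first-drawn
    subset.  With ``signed=True`` the signed maximum is taken instead of the
    absolute one.
    """
    sub = reports.dropna(subset=[measure]).reset_index(drop=True)
    q = len(sub)
    k = int(np.floor(q * fraction))
    if q < 6 or k < 3:
        raise InsufficientDataError(f"need >= 6 scored reports (have {q}, subset size {k})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = sub[measure].astype(float).to_numpy()
    d = sub["duration_min"].astype(float).to_numpy()
    best_idx, best_r, best_key = None, np.nan, -np.inf
    candidate_r = np.empty(n_sets)
    for j in range(n_sets):
        idx = rng.choice(q, size=k, replace=False)
        r = _pearson(s[idx], d[idx])
        candidate_r[j] = r
        key = (r if signed else abs(r)) if np.isfinite(r) else -np.inf
        if key > best_key:
            best_key, best_r, best_idx = key, r, idx
    if best_idx is None:
        raise InsufficientDataError("every candidate subset had undefined correlation")
    finite = np.abs(candidate_r[np.isfinite(candidate_r)])
    pct = float(stats.percentileofscore(finite, abs(best_r), kind="mean"))
    return SubsampleResult(indices=best_idx, r=float(best_r), abs_r_percentile=pct,
                           candidate_r=candidate_r)


def correlation_percentile_curve(
    rs: ReportSet,
    measure: str = "happiness",
    method: str | None = None,
    n_sets: int = 100,
    fraction: float = 0.5,
    n_bins: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean |weighted - unweighted| by percentile of the selected-subset |r|.

    For each person (x method), the max-|r| half-subset is selected and the
    total-formula weighting difference is recomputed **on that subset**;
    persons are then ranked by the subset's |r| into ``n_bins`` equal-count
    bins.  Rising mean |diff| across bins shows that, where the correlation
    is strong, duration weighting does move overall wellbeing.
    """
    df = rs.reports
    if method is not None:
        df = df[df["method"] == method]
    rng = np.random.default_rng(seed)
    rows = []
    for (pid, meth), g in df.groupby(["person_id", "method"], sort=False):
        sub = g.dropna(subset=[measure]).reset_index(drop=True)
        try:
            sel = max_correlation_subsample(
                sub, measure, n_sets=n_sets, fraction=fraction, seed=rng
            )
        except InsufficientDataError:
            continue
        chosen = sub.iloc[sel.indices]
        diff = total_weighted_swb(chosen, measure) - total_swb(chosen, measure)
        rows.append(dict(person_id=pid, method=meth, abs_r=abs(sel.r), abs_diff=abs(diff)))
    per_person = pd.DataFrame(rows)
    if len(per_person) < n_bins:
        raise InsufficientDataError(f"need >= {n_bins} persons, have {len(per_person)}")
    ranks = per_person["abs_r"].rank(method="first")
    per_person["bin"] = pd.qcut(ranks, n_bins, labels=False) + 1
    curve = (
        per_person.groupby("bin")
        .agg(n=("abs_r", "size"), mean_abs_r=("abs_r", "mean"), mean_abs_diff=("abs_diff", "mean"))
        .reset_index()
    )
    curve.attrs["per_person"] = per_person
    return curve


def drivers_regression(features: pd.DataFrame, outcome: str = "abs") -> dict:
    """OLS of the weighting difference on standardized driver features.

    ``outcome="abs"`` regresses |diff_total| on |r|, sd_intensity and
    sd_duration (the magnitude framing); ``outcome="signed"`` regresses the
    signed diff_total on signed r and the SDs.  All variables are
    z-standardized, so coefficients are comparable and the dominant driver
    is the one with the largest absolute coefficient.  Constant predictors
    are dropped with a warning.
    """
    feats = features.dropna(subset=["r_intensity_duration"]).copy()
    if len(feats) < 10:
        raise InsufficientDataError("need >= 10 persons with complete features")
    if outcome == "abs":
        y = feats["diff_total"].abs()
        x = pd.DataFrame(
            {
                "r": feats["r_intensity_duration"].abs(),
                "sd_intensity": feats["sd_intensity"],
                "sd_duration": feats["sd_duration"],
            }
        )
    elif outcome == "signed":
        y = feats["diff_total"]
        x = pd.DataFrame(
            {
                "r": feats["r_intensity_duration"],
                "sd_intensity": feats["sd_intensity"],
                "sd_duration": feats["sd_duration"],
            }
        )
    else:
        raise ValueError("outcome must be 'abs' or 'signed'")
    kept = []
    for col in list(x.columns):
        if x[col].std(ddof=1) == 0:
            warnings.warn(f"constant predictor {col!r} dropped from drivers regression")
            x = x.drop(columns=col)
        else:
            kept.append(col)
    xz = (x - x.mean()) / x.std(ddof=1)
    yz = (y - y.mean()) / (y.std(ddof=1) if y.std(ddof=1) > 0 else 1.0)
    fit = sm.OLS(yz.to_numpy(), sm.add_constant(xz.to_numpy())).fit()
    params = dict(zip(kept, fit.params[1:]))
    bse = dict(zip(kept, fit.bse[1:]))
    dominance = sorted(kept, key=lambda c: -abs(params[c]))
    return dict(
        params=params, bse=bse, r_squared=float(fit.rsquared),
        dominance=dominance, n=len(feats), fit=fit,
    )


def carryover_regression(rs: ReportSet, measure: str = "happiness", method: str | None = None) -> dict:
    """Emotional-lag regression within person-day episode sequences.

    Pools lag-1 pairs of consecutive episodes within each person x method x
    day (pairs never cross a day boundary), person-mean centers the current
    score and both lagged predictors, standardizes, and fits

        score_t ~ score_{t-1} + duration_{t-1}

    The previous episode's feeling is a "stronger predictor" than its
    duration when its absolute standardized coefficient is larger.
    """
    df = rs.reports
    if method is not None:
        df = df[df["method"] == method]
    df = df.dropna(subset=[measure])
    pairs = []
    for (pid, meth, day), g in df.groupby(["person_id", "method", "day_index"], sort=False):
        g = g.sort_values("seq_index", kind="stable")
        s = g[measure].astype(float).to_numpy()
        d = g["duration_min"].astype(float).to_numpy()
        for t in range(1, len(g)):
            pairs.append((pid, s[t], s[t - 1], d[t - 1]))
    if not pairs:
        raise InsufficientDataError("no within-day lag pairs")
    tab = pd.DataFrame(pairs, columns=["person_id", "y", "prev_score", "prev_duration"])
    centred = tab[["y", "prev_score", "prev_duration"]] - tab.groupby("person_id")[
        ["y", "prev_score", "prev_duration"]
    ].transform("mean")
    sds = centred.std(ddof=1)
    bad = ~(sds > 0)  # zero variance, or NaN from a single lag pair
    if bad.any():
        raise InsufficientDataError(
            f"degenerate carryover fit: zero variance in {list(sds.index[bad])}"
        )
    z = centred / sds
    fit = sm.OLS(z["y"].to_numpy(), sm.add_constant(z[["prev_score", "prev_duration"]].to_numpy())).fit()
    names = ["prev_score", "prev_duration"]
    params = dict(zip(names, fit.params[1:]))
    bse = dict(zip(names, fit.bse[1:]))
    return dict(
        params=params, bse=bse, n_pairs=len(tab),
        stronger_predictor=max(names, key=lambda c: abs(params[c])), fit=fit,
    )
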