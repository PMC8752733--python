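"""Equivalence testing of weighted vs unweighted wellbeing scores.

The scientific question is negative: does duration weighting change a
person's overall wellbeing score by a practically meaningful amount?  The
margin of practical meaninglessness is 0.1 points — 1% of the 0-10 response
scale (major life events move wellbeing by roughly 5%, so 1% is a
deliberately easy bar for a difference to clear).

Equivalence is established with the TOST procedure (two one-sided paired
t-tests against -margin and +margin); the reported TOST p-value is the
larger of the two one-sided p-values, and ``equivalent`` is True exactly
when that p-value is below alpha — equivalently, when the (1 - 2*alpha)
confidence interval of the mean difference lies strictly inside
(-margin, +margin).  The plain 95% CI is reported alongside.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.weightstats import DescrStatsW

from .reportset import DRM, EMA

__all__ = [
    "EquivalenceResult",
    "tost_equivalence",
    "equivalence_suite",
    "stratified_equivalence",
    "median_split",
    "DEFAULT_MARGIN",
]

#: 1% of the 0-10 scale range
DEFAULT_MARGIN = 0.1


class InsufficientDataError(ValueError):
    pass


@dataclasses.dataclass
class EquivalenceResult:
    """Outcome of one TOST equivalence test on paired differences."""

    n: int
    mean_diff: float
    ci95: tuple[float, float]
    ci_tost: tuple[float, float]  # (1 - 2*alpha) CI, the TOST-dual interval
    tost_p: float
    equivalent: bool
    margin: float
    alpha: float
    method: str | None = None
    measure: str | None = None
    formula_family: str | None = None
    stratum: str | None = None


def _ci(x: np.ndarray, level: float) -> tuple[float, float]:
    n, m = len(x), x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return (m, m)
    half = stats.t.ppf(0.5 + level / 2, n - 1) * sd / np.sqrt(n)
    return (m - half, m + half)


def tost_equivalence(
    diffs, margin: float = DEFAULT_MARGIN, alpha: float = 0.05
) -> EquivalenceResult:
    """TOST on per-person paired differences against a symmetric margin."""
    if margin <= 0:
        raise ValueError(f"margin must be > 0, got {margin}")
    x = np.asarray(diffs, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("TOST needs at least 2 paired differences")
    if not np.isfinite(x).all():
        raise ValueError("differences must be finite")
    if x.std(ddof=1) == 0:
        # degenerate sample: equivalence is decided by the constant itself
        inside = abs(x.mean()) < margin
        p = 0.0 if inside else 1.0
        return EquivalenceResult(
            n=len(x), mean_diff=float(x.mean()), ci95=(x.mean(), x.mean()),
            ci_tost=(x.mean(), x.mean()), tost_p=p, equivalent=inside,
            margin=margin, alpha=alpha,
        )
    p, (t1, p1, _), (t2, p2, _) = DescrStatsW(x).ttost_mean(-margin, margin)
    return EquivalenceResult(
        n=len(x),
        mean_diff=float(x.mean()),
        ci95=_ci(x, 0.95),
        ci_tost=_ci(x, 1 - 2 * alpha),
        tost_p=float(p),
        equivalent=bool(p < alpha),
        margin=margin,
        alpha=alpha,
    )


def equivalence_suite(
    summaries: pd.DataFrame,
    margin: float = DEFAULT_MARGIN,
    alpha: float = 0.05,
    stratum: str | None = None,
) -> pd.DataFrame:
    """One TOST per method x measure x {total, daily} cell.

    ``summaries`` is the per-person table from
    :func:`swbweight.aggregate.summarize_persons`.  Cells with fewer than two
    persons are marked not-computable (``equivalent`` is NA) rather than
    aborting the run.
    """
    rows = []
    methods = [m for m in (EMA, DRM) if m in set(summaries.get("method", []))]
    measures = list(dict.fromkeys(summaries.get("measure", [])))
    for method in methods:
        for measure in measures:
            cell = summaries[(summaries["method"] == method) & (summaries["measure"] == measure)]
            for family, col in (("total", "diff_total"), ("daily", "diff_daily")):
                base = dict(method=method, measure=measure, formula_family=family,
                            stratum=stratum, margin=margin, alpha=alpha)
                if len(cell) < 2:
                    rows.append(dict(**base, n=len(cell), mean_diff=np.nan,
                                     ci95_low=np.nan, ci95_high=np.nan,
                                     tost_p=np.nan, equivalent=pd.NA))
                    continue
                res = tost_equivalence(cell[col].to_numpy(), margin=margin, alpha=alpha)
                rows.append(dict(**base, n=res.n, mean_diff=res.mean_diff,
                                 ci95_low=res.ci95[0], ci95_high=res.ci95[1],
                                 tost_p=res.tost_p, equivalent=res.equivalent))
    out = pd.DataFrame(rows)
    if not out.empty:
        out["equivalent"] = out["equivalent"].astype("boolean")
    return out


def median_split(values: pd.Series, labels: tuple[str, str] = ("low", "high")) -> pd.Series:
    """Person-level median split of a continuous covariate.

    Values strictly above the median go to the second label.  A constant
    covariate collapses to a single stratum (with a warning).
    """
    med = values.median()
    if values.nunique() <= 1:
        warnings.warn("constant covariate: median split yields a single stratum")
        return pd.Series(labels[0], index=values.index)
    return pd.Series(np.where(values > med, labels[1], labels[0]), index=values.index)


def stratified_equivalence(
    summaries: pd.DataFrame,
    strata: pd.Series,
    margin: float = DEFAULT_MARGIN,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the equivalence suite within each person stratum.

    ``strata`` maps person_id -> stratum label and must assign every person
    in ``summaries`` to exactly one stratum.
    """
    missing = set(summaries["person_id"]) - set(strata.index)
    if missing:
        raise ValueError(f"persons without a stratum: {sorted(missing)[:5]} ...")
    out = []
    for label in pd.unique(strata):
        persons = strata.index[strata == label]
        sub = summaries[summaries["person_id"].isin(persons)]
        out.append(equivalence_suite(sub, margin=margin, alpha=alpha, stratum=str(label)))
    return pd.concat(out, ignore_index=True)
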