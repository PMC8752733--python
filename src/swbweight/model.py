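"""Model/Results surface tying the pipeline together.

:class:`DurationWeightingModel` is built from a report table (a
:class:`~swbweight.reportset.ReportSet`, a tidy DataFrame, or a CSV file);
``fit()`` runs the canonical preprocessing, computes all four per-person
aggregation scores, and tests weighted-vs-unweighted equivalence in every
method x measure x {total, daily} cell.  The returned
:class:`DurationWeightingResults` carries the estimates and exposes the
post-hoc analyses (stratified re-runs, driver features and regression,
the max-correlation subsampling curve, the carryover regression) plus a
``summary()`` text table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import aggregate, drivers, equivalence, preprocess
from .reportset import DRM, EMA, ReportSet, read_reports

__all__ = ["DurationWeightingModel", "DurationWeightingResults"]


class DurationWeightingModel:
    """Does weighting wellbeing reports by activity duration change overall SWB?

    Parameters
    ----------
    data
        ReportSet, tidy DataFrame in the canonical long format, or both
        happiness and worthwhileness columns present.
    margin
        Equivalence margin in score points (default 0.1 = 1% of the scale).
    alpha
        Significance level of the two one-sided tests.
    preprocess
        Run the canonical exclusion pipeline (12-h filter, EMA dedupe,
        participant inclusion, EMA doubling) before aggregating.
    measures
        Which intensity measures to analyse.

    Examples
    --------
    >>> from swbweight import DurationWeightingModel, SyntheticConfig, generate_cohort
    >>> rs = generate_cohort(SyntheticConfig(n_persons=60, seed=7))
    >>> res = DurationWeightingModel(rs).fit()
    >>> bool(res.equivalence["equivalent"].all())
    True
    """

    def __init__(
        self,
        data,
        margin: float = equivalence.DEFAULT_MARGIN,
        alpha: float = 0.05,
        preprocess: bool = True,
        measures=aggregate.MEASURES,
        **preprocess_kwargs,
    ):
        if isinstance(data, ReportSet):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            self.data = ReportSet(data, validate=False)
        else:
            raise TypeError("data must be a ReportSet or a tidy DataFrame; see from_csv")
        self.margin = margin
        self.alpha = alpha
        self.preprocess = preprocess
        self.preprocess_kwargs = preprocess_kwargs
        self.measures = tuple(measures)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DurationWeightingModel":
        return cls(read_reports(path), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DurationWeightingModel":
        return cls(ReportSet(df, validate=False), **kwargs)

    def fit(self) -> "DurationWeightingResults":
        rs = self.data
        if self.preprocess:
            rs = preprocess.preprocess_pipeline(rs, **self.preprocess_kwargs)
        summaries = aggregate.summarize_persons(rs, self.measures)
        if summaries.empty:
            raise ValueError("no scored reports survive preprocessing")
        eq = equivalence.equivalence_suite(summaries, margin=self.margin, alpha=self.alpha)
        return DurationWeightingResults(self, rs, summaries, eq)


class DurationWeightingResults:
    """Fitted estimates, equivalence tests and post-hoc probes."""

    def __init__(self, model, reports: ReportSet, summaries: pd.DataFrame, eq: pd.DataFrame):
        self.model = model
        self.reports = reports
        self.summaries = summaries
        self.equivalence = eq

    # ---- descriptives -------------------------------------------------
    @property
    def descriptives(self) -> pd.DataFrame:
        return aggregate.summarize_cohort(self.reports, self.model.measures)

    def compare_method_durations(self) -> dict:
        return aggregate.compare_method_durations(self.reports)

    # ---- post hocs ----------------------------------------------------
    def stratified(self, strata: pd.Series) -> pd.DataFrame:
        return equivalence.stratified_equivalence(
            self.summaries, strata, margin=self.model.margin, alpha=self.model.alpha
        )

    def variance_strata(self, variable: str = "duration", measure: str = "happiness") -> pd.Series:
        """Median-split persons by their within-person SD of duration/intensity."""
        feats = drivers.driver_features_table(self.reports, measure)
        col = "sd_duration" if variable == "duration" else "sd_intensity"
        per_person = feats.groupby("person_id")[col].mean()
        return equivalence.median_split(per_person)

    def driver_features(self, measure: str = "happiness", method: str | None = None) -> pd.DataFrame:
        return drivers.driver_features_table(self.reports, measure, method)

    def drivers_regression(self, measure: str = "happiness", method: str = EMA, outcome: str = "abs") -> dict:
        return drivers.drivers_regression(self.driver_features(measure, method), outcome)

    def correlation_percentile_curve(self, measure: str = "happiness", method: str = EMA, **kw) -> pd.DataFrame:
        return drivers.correlation_percentile_curve(self.reports, measure, method, **kw)

    def carryover(self, measure: str = "happiness", method: str = DRM) -> dict:
        return drivers.carryover_regression(self.reports, measure, method)

    # ---- presentation -------------------------------------------------
    def plot_weighted_vs_unweighted(self, measure: str = "happiness", method: str = EMA, ax=None):
        """Per-person scatter of duration-weighted vs unweighted total SWB."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        sub = self.summaries.query("measure == @measure and method == @method")
        ax.scatter(sub["total_swb"], sub["total_weighted_swb"], s=12, alpha=0.6)
        lim = (0, 10)
        ax.plot(lim, lim, lw=1, color="grey")
        ax.set_xlim(lim); ax.set_ylim(lim)
        ax.set_xlabel(f"total {measure} (unweighted)")
        ax.set_ylabel(f"total {measure} (duration-weighted)")
        ax.set_title(f"{method}: duration weighting vs plain mean")
        return ax

    def summary(self) -> str:
        """Human-readable account of the fit."""
        lines = [
            "Duration-weighted vs unweighted subjective wellbeing",
            "=" * 60,
            f"reports: {len(self.reports)}   persons: {len(self.reports.persons)}   "
            f"margin: {self.model.margin}   alpha: {self.model.alpha}",
            "",
            "Equivalence of weighted and unweighted scores (TOST):",
        ]
        hdr = f"{'method':<6} {'measure':<15} {'family':<7} {'n':>5} {'mean diff':>10} {'95% CI':>20} {'TOST p':>9} {'equiv':>6}"
        lines.append(hdr)
        lines.append("-" * len(hdr))
        for row in self.equivalence.itertuples(index=False):
            ci = f"[{row.ci95_low:+.3f}, {row.ci95_high:+.3f}]" if np.isfinite(row.ci95_low) else "n/a"
            eqs = {True: "yes", False: "NO"}.get(row.equivalent, "n/a") if row.equivalent is not pd.NA else "n/a"
            md = f"{row.mean_diff:+.4f}" if np.isfinite(row.mean_diff) else "n/a"
            lines.append(
                f"{row.method:<6} {row.measure:<15} {row.formula_family:<7} {row.n:>5} "
                f"{md:>10} {ci:>20} {row.tost_p:>9.2e} {eqs:>6}"
            )
        lines.append("")
        lines.append("equivalent = mean weighted-unweighted difference established")
        lines.append(f"inside +/-{self.model.margin} points (1% of the 0-10 scale).")
        return "\n".join(lines)
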