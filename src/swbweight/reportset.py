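"""Long-format momentary-wellbeing report container and CSV round-trip.

One row per report: either an EMA prompt answered in the moment, or a DRM
episode reconstructed the next morning.  Both carry an activity label, the
activity's duration in minutes and integer 0-10 intensity scores for
happiness and (optionally) worthwhileness.

The canonical on-disk dialect is a tidy UTF-8 CSV with the column order in
:data:`CANONICAL_COLUMNS`; empty strings encode missing optional fields.
Unknown extra columns are preserved verbatim so that person-level covariates
can ride along for stratified re-runs.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "EMA",
    "DRM",
    "EMA_GRID_STEP",
    "EMA_GRID_MAX",
    "ReportSet",
    "Violation",
    "SchemaError",
    "ValidationError",
    "read_reports",
    "write_reports",
    "validate_reportset",
]

EMA = "EMA"
DRM = "DRM"

#: canonical CSV column order; extra columns are appended after these
CANONICAL_COLUMNS = [
    "person_id",
    "method",
    "day_index",
    "seq_index",
    "clock_start",
    "clock_end",
    "activity",
    "duration_min",
    "happiness",
    "worthwhileness",
]

#: EMA duration picker: 10-minute increments from 10 min to 4 h 10 min
EMA_GRID_STEP = 10
EMA_GRID_MAX = 250

_KEY = ["person_id", "method", "day_index", "seq_index"]

# optional integer-valued columns use pandas' nullable Int64 so that missing
# values survive a CSV round trip without becoming floats
_INT_COLS = ["day_index", "seq_index", "duration_min", "happiness"]
_OPT_INT_COLS = ["clock_start", "clock_end", "worthwhileness"]


class SchemaError(ValueError):
    """The file's header does not name the mandatory columns."""


class ValidationError(ValueError):
    """Row-level invariant violations in strict mode."""

    def __init__(self, violations: Sequence["Violation"]):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations[:10])
        more = "" if len(self.violations) <= 10 else f" (+{len(self.violations) - 10} more)"
        super().__init__(f"{len(self.violations)} invalid report(s): {lines}{more}")


@dataclasses.dataclass(frozen=True)
class Violation:
    """A single invariant violation, identified by the report key and rule."""

    key: tuple
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.key}: [{self.rule}] {self.message}"


class ReportSet:
    """An ordered, validated collection of wellbeing reports.

    Parameters
    ----------
    reports
        DataFrame with at least the canonical columns (see
        :data:`CANONICAL_COLUMNS`); extra columns are kept.
    provenance
        Append-only pipeline history.  Each preprocessing step adds a line;
        the history is never rewritten.
    ema_doubled
        Whether EMA durations have already been doubled (the analysis-stage
        adjustment for prompts interrupting an activity mid-episode).  Grid
        validation scales accordingly.
    """

    def __init__(
        self,
        reports: pd.DataFrame,
        provenance: Iterable[str] | None = None,
        ema_doubled: bool = False,
        validate: bool = True,
    ):
        df = reports.copy()
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        for col in _INT_COLS:
            df[col] = df[col].astype("int64") if df[col].notna().all() else df[col]
        for col in _OPT_INT_COLS:
            df[col] = df[col].astype("Int64")
        df["person_id"] = df["person_id"].astype(str)
        df["method"] = df["method"].astype(str)
        df["activity"] = df["activity"].astype(str)
        # canonical columns first, extras after, row order preserved
        extras = [c for c in df.columns if c not in CANONICAL_COLUMNS]
        self._df = df[CANONICAL_COLUMNS + extras].reset_index(drop=True)
        self.provenance: list[str] = list(provenance or [])
        self.ema_doubled = bool(ema_doubled)
        if validate:
            violations = validate_reportset(self)
            if violations:
                raise ValidationError(violations)

    # ------------------------------------------------------------------
    @property
    def reports(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def persons(self) -> list[str]:
        return list(dict.fromkeys(self._df["person_id"]))

    def equals(self, other: "ReportSet") -> bool:
        """Field-for-field equality of the report tables (ignores provenance)."""
        a, b = self._df, other._df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        return a.fillna(-1).reset_index(drop=True).equals(b.fillna(-1).reset_index(drop=True))

    def with_reports(self, df: pd.DataFrame, note: str, ema_doubled: bool | None = None) -> "ReportSet":
        """New ReportSet with replaced rows and one provenance line appended."""
        return ReportSet(
            df,
            provenance=self.provenance + [note],
            ema_doubled=self.ema_doubled if ema_doubled is None else ema_doubled,
            validate=False,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ReportSet({len(self)} reports, {len(self.persons)} persons, "
            f"ema_doubled={self.ema_doubled})"
        )


def _ema_grid_violation(dur: int, doubled: bool) -> bool:
    step = EMA_GRID_STEP * (2 if doubled else 1)
    lo, hi = step, EMA_GRID_MAX * (2 if doubled else 1)
    return not (lo <= dur <= hi and dur % step == 0)


def validate_reportset(rs: ReportSet) -> list[Violation]:
    """Check every report- and set-level invariant; violations are data.

    Rules checked per report: score bounds (0-10 integers), positive duration,
    the EMA duration grid, and DRM clock consistency
    (``clock_end - clock_start`` modulo midnight equals ``duration_min``).
    Set-level: uniqueness of (person_id, method, day_index, seq_index).
    The check is idempotent and independent of report order.
    """
    df = rs.reports
    out: list[Violation] = []

    def key(row) -> tuple:
        return (row.person_id, row.method, row.day_index, row.seq_index)

    for row in df.itertuples(index=False):
        if row.method not in (EMA, DRM):
            out.append(Violation(key(row), "method", f"unknown method {row.method!r}"))
            continue
        if not (0 <= row.happiness <= 10):
            out.append(Violation(key(row), "score-range", f"happiness {row.happiness} outside 0-10"))
        if row.worthwhileness is not pd.NA and not (0 <= row.worthwhileness <= 10):
            out.append(
                Violation(key(row), "score-range", f"worthwhileness {row.worthwhileness} outside 0-10")
            )
        if row.duration_min <= 0:
            out.append(Violation(key(row), "duration-positive", f"duration {row.duration_min} <= 0"))
        elif row.method == EMA and _ema_grid_violation(int(row.duration_min), rs.ema_doubled):
            out.append(
                Violation(
                    key(row),
                    "ema-grid",
                    f"EMA duration {row.duration_min} not on the "
                    f"{'doubled ' if rs.ema_doubled else ''}10-minute grid [10, 250]"
                    + (" x2" if rs.ema_doubled else ""),
                )
            )
        if row.method == DRM:
            if row.clock_start is pd.NA or row.clock_end is pd.NA:
                out.append(Violation(key(row), "drm-clock", "DRM episode lacks clock_start/clock_end"))
            else:
                span = (int(row.clock_end) - int(row.clock_start)) % 1440
                span = span if span > 0 else int(row.clock_end) - int(row.clock_start)
                if span != int(row.duration_min):
                    out.append(
                        Violation(
                            key(row),
                            "drm-clock",
                            f"clock span {span} != duration_min {row.duration_min}",
                        )
                    )

    dup = df.duplicated(subset=_KEY, keep=False)
    if dup.any():
        for row in df.loc[dup].drop_duplicates(subset=_KEY).itertuples(index=False):
            out.append(Violation(key(row), "unique-key", "duplicate (person, method, day, seq) key"))
    return out


def read_reports(path, schema_strict: bool = True, ema_doubled: bool = False) -> ReportSet:
    """Read the canonical long-format CSV into a validated ReportSet.

    With ``schema_strict`` (default) any invariant violation raises
    :class:`ValidationError` naming the offending rows; the header must name
    every canonical column either way.
    """
    df = pd.read_csv(path, dtype={"person_id": str, "activity": str}, keep_default_na=True)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    rs = ReportSet(
        df,
        provenance=[f"read_reports: {path} ({len(df)} rows)"],
        ema_doubled=ema_doubled,
        validate=False,
    )
    if schema_strict:
        violations = validate_reportset(rs)
        if violations:
            raise ValidationError(violations)
    return rs


def write_reports(rs: ReportSet, path):
    """Write the canonical CSV (lossless for all fields; empty = missing)."""
    df = rs.reports.copy()
    df.to_csv(path, index=False)
    return path
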