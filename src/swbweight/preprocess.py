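"""Report-level exclusions and participant-level inclusion rules.

The canonical pipeline order is fixed:

1. :func:`filter_long_durations` — drop reports longer than 12 h (strict),
   applied to raw, pre-doubling durations;
2. :func:`dedupe_ema` — drop the later of any two EMA reports started within
   less than 15 min of each other (likely duplicates);
3. :func:`select_participants` — keep persons with more than 20 EMA reports
   (strict) and at least 5 DRM reports (inclusive);
4. :func:`double_ema_durations` — double every EMA duration, because an EMA
   prompt interrupts the activity roughly mid-episode; DRM episodes are
   untouched.

All boundary semantics are read strictly: a 720-min report survives the 12-h
filter, a pair exactly 15 min apart survives deduplication, a person with
exactly 20 EMA reports is excluded.  Every step appends to provenance and
never adds reports; steps 1-3 are idempotent, step 4 refuses re-application.
"""

from __future__ import annotations

from .reportset import DRM, EMA, ReportSet

__all__ = [
    "filter_long_durations",
    "dedupe_ema",
    "double_ema_durations",
    "select_participants",
    "preprocess_pipeline",
    "DoubleApplicationError",
    "CannotDeduplicateError",
]


class DoubleApplicationError(RuntimeError):
    """EMA durations were already doubled on this ReportSet."""


class CannotDeduplicateError(ValueError):
    """EMA reports carry no time information to deduplicate on."""


def filter_long_durations(rs: ReportSet, max_minutes: int = 720) -> ReportSet:
    """Drop reports whose duration exceeds ``max_minutes`` (strictly)."""
    if rs.ema_doubled:
        raise DoubleApplicationError(
            "filter_long_durations must run on raw (pre-doubling) durations"
        )
    df = rs.reports
    keep = df["duration_min"] <= max_minutes
    removed = int((~keep).sum())
    return rs.with_reports(
        df[keep], f"filter_long_durations(max={max_minutes}): removed {removed} report(s)"
    )


def dedupe_ema(rs: ReportSet, window_minutes: int = 15) -> ReportSet:
    """Drop the later EMA report of any pair started < ``window_minutes`` apart.

    A sequential scan per person x day over EMA reports ordered by
    ``clock_start``: a report survives iff it starts at least
    ``window_minutes`` after the last *surviving* report.  DRM episodes are
    untouched.
    """
    df = rs.reports
    ema = df["method"] == EMA
    if ema.any() and df.loc[ema, "clock_start"].isna().any():
        raise CannotDeduplicateError("EMA report(s) lack clock_start; cannot deduplicate")
    drop: list[int] = []
    for _, g in df[ema].groupby(["person_id", "day_index"], sort=False):
        g = g.sort_values("clock_start", kind="stable")
        last_kept = None
        for idx, start in zip(g.index, g["clock_start"].astype(int)):
            if last_kept is not None and start - last_kept < window_minutes:
                drop.append(idx)
            else:
                last_kept = start
    return rs.with_reports(
        df.drop(index=drop),
        f"dedupe_ema(window={window_minutes}): removed {len(drop)} duplicate EMA report(s)",
    )


def double_ema_durations(rs: ReportSet) -> ReportSet:
    """Double every EMA duration (interrupted-mid-episode correction)."""
    if rs.ema_doubled:
        raise DoubleApplicationError("EMA durations already doubled")
    df = rs.reports.copy()
    ema = df["method"] == EMA
    df.loc[ema, "duration_min"] = df.loc[ema, "duration_min"] * 2
    return rs.with_reports(
        df, f"double_ema_durations: doubled {int(ema.sum())} EMA duration(s)", ema_doubled=True
    )


def select_participants(rs: ReportSet, min_ema: int = 20, min_drm: int = 5) -> ReportSet:
    """Keep persons with more than ``min_ema`` EMA and at least ``min_drm`` DRM reports."""
    df = rs.reports
    counts = df.pivot_table(index="person_id", columns="method", values="day_index", aggfunc="size")
    counts = counts.reindex(columns=[EMA, DRM]).fillna(0).astype(int)
    ok = counts[(counts[EMA] > min_ema) & (counts[DRM] >= min_drm)].index
    dropped = sorted(set(df["person_id"]) - set(ok))
    note = (
        f"select_participants(ema>{min_ema}, drm>={min_drm}): "
        f"kept {len(ok)}, dropped {len(dropped)} person(s)"
        + (f" [{', '.join(dropped[:20])}]" if dropped else "")
    )
    return rs.with_reports(df[df["person_id"].isin(ok)], note)


def preprocess_pipeline(
    rs: ReportSet,
    max_minutes: int = 720,
    dedupe_window: int = 15,
    min_ema: int = 20,
    min_drm: int = 5,
    double_ema: bool = True,
) -> ReportSet:
    """Run the canonical exclusion pipeline in its fixed order."""
    rs = filter_long_durations(rs, max_minutes)
    rs = dedupe_ema(rs, dedupe_window)
    rs = select_participants(rs, min_ema, min_drm)
    if double_ema:
        rs = double_ema_durations(rs)
    return rs
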