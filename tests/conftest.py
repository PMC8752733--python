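import hypothesis
import pandas as pd
import pytest

from swbweight import ReportSet, SyntheticConfig, generate_cohort

hypothesis.settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("ci")


def report_row(
    person="p1",
    method="EMA",
    day=1,
    seq=1,
    dur=60,
    hap=7,
    worth=None,
    clock_start=None,
    clock_end=None,
    activity="working",
):
    """One canonical report row; DRM rows get consistent clocks by default."""
    if method == "DRM" and clock_start is None:
        clock_start = 480
        clock_end = 480 + dur
    return dict(
        person_id=person,
        method=method,
        day_index=day,
        seq_index=seq,
        clock_start=clock_start,
        clock_end=clock_end,
        activity=activity,
        duration_min=dur,
        happiness=hap,
        worthwhileness=worth,
    )


def make_reportset(rows, validate=True, **kwargs):
    return ReportSet(pd.DataFrame(rows), validate=validate, **kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """30-person, 10-day cohort with mild intensity-duration correlation."""
    return generate_cohort(SyntheticConfig(n_persons=30, n_days=10, rho=0.3, seed=42))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with zero intensity-duration correlation."""
    return generate_cohort(SyntheticConfig(n_persons=40, n_days=14, rho=0.0, seed=7))
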