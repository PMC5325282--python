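import pytest

from eagle_demography.rates import canonical_rates
from eagle_demography.telemetry_io import (
    CaptureHistory,
    NestSurveyRecord,
    SeasonInterval,
)


@pytest.fixture(scope="session")
def all_deaths_rates():
    return canonical_rates("all_deaths")


@pytest.fixture(scope="session")
def turbine_rates():
    return canonical_rates("turbine_censored")


@pytest.fixture(scope="session")
def human_rates():
    return canonical_rates("human_censored")


@pytest.fixture(scope="session")
def nest_surveys_1996_2000():
    """Five years of published nest-survey counts."""
    return [
        NestSurveyRecord(1996, 59, 39, 27),
        NestSurveyRecord(1997, 59, 35, 22),
        NestSurveyRecord(1998, 64, 37, 29),
        NestSurveyRecord(1999, 69, 62, 40),
        NestSurveyRecord(2000, 67, 31, 22),
    ]


def make_history(
    ind="A1",
    sex="female",
    stage="juvenile",
    entry=SeasonInterval(1994, "Summer"),
    states=("alive-detected",),
    cause=None,
):
    """Build a history whose records start at ``entry`` and follow the
    given per-interval states."""
    iv = entry
    records = []
    for s in states:
        records.append((iv, s))
        iv = iv.next()
    return CaptureHistory(ind, sex, stage, entry, records, cause)


@pytest.fixture
def history_factory():
    return make_history
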