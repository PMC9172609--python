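import datetime as dt

import pytest
from hypothesis import settings

import surgecast as sc
from surgecast.io import slice_series

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def weekday_only():
    """Noiseless scenario where the count is a pure function of the weekday."""
    params, holidays, streams = sc.scenario_data("WEEKDAY_ONLY", seed=1)
    return params, holidays, streams


@pytest.fixture(scope="session")
def calibrated():
    """The calibrated 4-year Poisson scenario (2016-2019, ~10 holidays/yr)."""
    params, holidays, streams = sc.scenario_data("CALIBRATED_DEFAULT", seed=1)
    return params, holidays, streams


@pytest.fixture(scope="session")
def calibrated_history(calibrated):
    _, _, streams = calibrated
    return slice_series(streams["overall"], dt.date(2016, 1, 1), dt.date(2018, 12, 31))


@pytest.fixture()
def toy_week_holidays():
    """Mon 2019-04-22 .. Sun 2019-04-28 with Thursday 2019-04-25 a holiday."""
    return sc.HolidayCalendar.from_dates([dt.date(2019, 4, 25)])
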