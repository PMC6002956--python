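"""Shared fixtures: a small synthetic experiment generated at test time."""

from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd
import pytest

from damkit import FlySpec, LightCalendar, generate_monitor


@pytest.fixture(scope="session")
def calendar() -> LightCalendar:
    """3 LD days then 7 DD days, lights on at 06:00."""
    return LightCalendar(ld_start=date(2017, 1, 2), ld_end=date(2017, 1, 4),
                         dd_start=date(2017, 1, 5), dd_end=date(2017, 1, 11),
                         light_onset=time(6, 0))


@pytest.fixture(scope="session")
def fixture_monitor(calendar):
    """One simulated monitor: 6 rhythmic square-wave flies, 1 fly that dies
    on Jan 7, 1 arrhythmic constant-rate fly, channels 9-32 empty."""
    specs = [FlySpec(baseline_rate=0.2, amplitude=1.5, period_h=24.0,
                     phase_h=6.0, waveform="square",
                     day_active_fraction=0.8) for _ in range(6)]
    specs.append(FlySpec(baseline_rate=1.0, death_day=date(2017, 1, 7)))
    specs.append(FlySpec(baseline_rate=1.0))
    return generate_monitor(specs, calendar, 1.0, seed=2017,
                            monitor_id="MonitorA")


def minute_series(values, start=datetime(2017, 1, 2, 6, 0)) -> pd.Series:
    """A 1-min count series starting at the given timestamp."""
    idx = pd.DatetimeIndex([start + timedelta(minutes=k)
                            for k in range(len(values))])
    return pd.Series(np.asarray(values), index=idx, name="fly")


@pytest.fixture
def make_minute_series():
    return minute_series
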