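from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import settings

from phenosense import GpsFix, ScanSchedule, ScheduleBlock

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

START = datetime(2018, 5, 7, 0, 0, tzinfo=timezone.utc)


@pytest.fixture
def start():
    return START


@pytest.fixture
def week_schedule():
    """One week at the slowest study rate (8-minute scans)."""
    return ScanSchedule([ScheduleBlock(7, 8)])


def make_fixes(coords, t0=START, step_minutes=5.0, pid="p01"):
    """GpsFix sequence from (lat, lon) pairs at a regular cadence."""
    step = timedelta(minutes=step_minutes)
    return [GpsFix(pid, t0 + i * step, lat, lon)
            for i, (lat, lon) in enumerate(coords)]
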