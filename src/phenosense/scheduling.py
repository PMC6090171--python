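"""Scan schedules and data-completeness accounting.

The study protocol scanned GPS and Bluetooth simultaneously at a fixed
inter-scan interval that changed weekly: 3, 4, 5 and 8 minutes (20, 15, 12
and 7.5 scans per hour), one week each.  Over four weeks this schedules
(20 + 15 + 12 + 7.5) x 24 x 7 = 9156 scans per participant.  Completeness is
the percentage of those scheduled scan instants for which at least one
record was actually collected.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True, slots=True)
class ScheduleBlock:
    """One contiguous block of the protocol: `days` days at a fixed interval."""

    days: float
    interval_minutes: float

    def __post_init__(self) -> None:
        if self.days <= 0:
            raise ValueError("block duration must be positive")
        if self.interval_minutes <= 0:
            raise ValueError("scan interval must be positive")

    @property
    def scans_per_hour(self) -> float:
        return 60.0 / self.interval_minutes

    @property
    def duration(self) -> timedelta:
        return timedelta(days=self.days)


@dataclass(frozen=True)
class ScanSchedule:
    """Ordered weekly blocks of inter-scan intervals."""

    blocks: tuple[ScheduleBlock, ...] = ()

    def __init__(self, blocks: Iterable[ScheduleBlock | tuple[float, float]] = ()):
        object.__setattr__(
            self,
            "blocks",
            tuple(b if isinstance(b, ScheduleBlock) else ScheduleBlock(*b)
                  for b in blocks),
        )

    @property
    def total_duration(self) -> timedelta:
        return sum((b.duration for b in self.blocks), timedelta(0))

    def block_starts(self, start: datetime) -> list[datetime]:
        """Start instant of each block, given the study start."""
        out, t = [], start
        for b in self.blocks:
            out.append(t)
            t += b.duration
        return out

    def block_of(self, start: datetime, when: datetime) -> int | None:
        """Index of the block containing `when`, boundaries going to the later
        block; None if outside the study window."""
        t = start
        for i, b in enumerate(self.blocks):
            t_next = t + b.duration
            if t <= when < t_next:
                return i
            t = t_next
        return None


#: The feasibility-study protocol: one week each at 3, 4, 5 and 8 minute intervals.
STUDY_SCHEDULE = ScanSchedule(
    [ScheduleBlock(7, 3), ScheduleBlock(7, 4), ScheduleBlock(7, 5), ScheduleBlock(7, 8)]
)


def scheduled_scan_count(schedule: ScanSchedule) -> int:
    """Total number of scheduled scans: sum over blocks of scans/hour x 24 x days.

    Fractional scans-per-hour are allowed (an 8-minute interval gives 7.5);
    rounding to the nearest integer happens only on the final sum.  For the
    study schedule this is 9156.
    """
    total = sum(b.scans_per_hour * 24.0 * b.days for b in schedule.blocks)
    return int(round(total))


def scan_instants(schedule: ScanSchedule, start: datetime) -> list[datetime]:
    """Every scheduled scan instant, in order, given the study start time."""
    out: list[datetime] = []
    t_block = start
    for b in schedule.blocks:
        n = int(round(b.days * 24 * 60 / b.interval_minutes))
        step = timedelta(minutes=b.interval_minutes)
        out.extend(t_block + k * step for k in range(n))
        t_block += b.duration
    return out


@dataclass(frozen=True, slots=True)
class CompletenessReport:
    """Collected scans as a share of those scheduled, for one participant."""

    participant_id: str
    scheduled: int
    collected: int

    @property
    def pct(self) -> float:
        return 100.0 * self.collected / self.scheduled if self.scheduled else float("nan")

    @property
    def over_collected(self) -> bool:
        return self.collected > self.scheduled


def completeness(
    records: Sequence,
    schedule: ScanSchedule,
    start: datetime,
    participant_id: str,
) -> CompletenessReport:
    """Count scheduled scan instants that have at least one collected record.

    A scheduled instant counts as collected when some record for the
    participant falls within half the block's inter-scan interval of it, a
    tolerance that makes the accounting robust to clock jitter.  Records of
    any sensor kind may be mixed (the protocol scans Bluetooth and GPS on one
    schedule); the computation is invariant to record order and to duplicate
    records at one instant.
    """
    times = np.sort(np.array(
        [
            ((getattr(r, "scan_time", None) or r.timestamp) - start).total_seconds()
            for r in records
            if r.participant_id == participant_id
        ],
        dtype=float,
    ))
    collected = 0
    block_off = 0.0
    for b in schedule.blocks:
        n = int(round(b.days * 24 * 60 / b.interval_minutes))
        if times.size:
            offsets = block_off + np.arange(n) * b.interval_minutes * 60.0
            half = b.interval_minutes * 30.0
            lo = np.searchsorted(times, offsets - half, side="left")
            hi = np.searchsorted(times, offsets + half, side="right")
            collected += int(np.count_nonzero(hi > lo))
        block_off += b.days * 24 * 3600.0
    return CompletenessReport(participant_id, scheduled_scan_count(schedule), collected)
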