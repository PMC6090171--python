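"""Bluetooth social context: known/unknown devices and hourly profiles.

In an open study population, nearby Bluetooth phones are a coarse proxy for
the social density around a participant rather than a contact network.  A
device is *known* to a participant once it has been observed on at least 3
distinct local calendar days over the study; all others are *unknown*
(transient passers-by).  Averaging the number of known and unknown devices
per scan within each local hour of the day gives a 24-point social-context
profile per participant.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Mapping, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .sensor_io import DEFAULT_TZ, BluetoothSighting, get_tz

#: Minimum distinct observation days for a device to count as known.
MIN_KNOWN_DAYS = 3


@dataclass(frozen=True)
class DeviceCatalog:
    """Per-participant partition of observed devices into known/unknown."""

    days_seen: Mapping[str, frozenset]   # device_hash -> distinct local dates
    min_days: int = MIN_KNOWN_DAYS

    def is_known(self, device_hash: str) -> bool:
        return len(self.days_seen.get(device_hash, ())) >= self.min_days

    @property
    def known(self) -> frozenset:
        return frozenset(h for h, d in self.days_seen.items()
                         if len(d) >= self.min_days)

    @property
    def unknown(self) -> frozenset:
        return frozenset(h for h, d in self.days_seen.items()
                         if len(d) < self.min_days)


def classify_known_devices(
    sightings: Sequence[BluetoothSighting],
    min_days: int = MIN_KNOWN_DAYS,
    tz: str | ZoneInfo = DEFAULT_TZ,
) -> DeviceCatalog:
    """Catalog devices by distinct local calendar days observed.

    A day counts once per (device, local date) regardless of how many scans
    saw the device that day; a device is known iff its distinct-day count is
    at least ``min_days``.  Sightings should already be filtered to the
    phone device class.
    """
    tzinfo = get_tz(tz) if isinstance(tz, str) else tz
    days: dict[str, set] = {}
    for s in sightings:
        local_day = s.scan_time.astimezone(tzinfo).date()
        days.setdefault(s.device_hash, set()).add(local_day)
    return DeviceCatalog({h: frozenset(d) for h, d in days.items()}, min_days)


def hourly_context_profile(
    sightings: Sequence[BluetoothSighting],
    catalog: DeviceCatalog,
    tz: str | ZoneInfo = DEFAULT_TZ,
    scan_times: Sequence[datetime] | None = None,
) -> pd.DataFrame:
    """Average known/unknown device counts per scan, by local hour of day.

    Each scan (a distinct ``scan_time``) contributes one count of distinct
    known and distinct unknown device hashes; counts are averaged over all
    scans whose local start time falls in each hour 0-23.  Scans that
    detected no devices leave no trace in a sightings log, so callers who
    know the full scan schedule can pass ``scan_times`` to include empty
    scans in the denominator; by default the distinct scan times present in
    the log are used.

    Returns a 24-row DataFrame indexed by hour with columns ``mean_known``,
    ``mean_unknown`` and ``n_scans``; hours with no scans hold NaN means.
    """
    tzinfo = get_tz(tz) if isinstance(tz, str) else tz

    per_scan: dict[datetime, tuple[set, set]] = {}
    if scan_times is not None:
        for t in scan_times:
            per_scan[t] = (set(), set())
    for s in sightings:
        known, unknown = per_scan.setdefault(s.scan_time, (set(), set()))
        (known if catalog.is_known(s.device_hash) else unknown).add(s.device_hash)

    sums = np.zeros((24, 2))
    n_scans = np.zeros(24, dtype=int)
    for t, (known, unknown) in per_scan.items():
        h = t.astimezone(tzinfo).hour
        sums[h, 0] += len(known)
        sums[h, 1] += len(unknown)
        n_scans[h] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(n_scans[:, None] > 0, sums / np.maximum(n_scans, 1)[:, None],
                         np.nan)
    return pd.DataFrame(
        {"mean_known": means[:, 0], "mean_unknown": means[:, 1], "n_scans": n_scans},
        index=pd.RangeIndex(24, name="hour"),
    )
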