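"""Synthetic sensor-log generators with the structure the analysis assumes.

Raw study data cannot be redistributed (GPS especially would re-identify
participants), so every pipeline stage is exercised against generated logs
whose ground truth is known: multi-anchor GPS trajectories with a
controllable 24-hour rhythm, jitter and missing scans; Bluetooth logs with
a recurring known-device pool plus transient unknown devices following an
hour-of-day intensity; and linearly discharging batteries whose rate grows
with the scan rate.  All generators are pure functions of their scenario
(including its seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
import numpy as np

from .scheduling import STUDY_SCHEDULE, ScanSchedule, scan_instants
from .sensor_io import (
    DEFAULT_TZ,
    BatterySample,
    BluetoothSighting,
    GpsFix,
    PHONE_MAJOR_CLASS,
    get_tz,
    hash_device_id,
)
from .mobility import haversine_m

_M_PER_DEG_LAT = 6_371_000.0 * np.pi / 180.0

#: Five anchor locations around Sydney, all pairs >= 2 km apart.
DEFAULT_ANCHORS = (
    (-33.890, 151.210),   # home
    (-33.870, 151.210),   # work
    (-33.890, 151.240),   # gym
    (-33.910, 151.190),   # shops
    (-33.865, 151.245),   # friend
)

DEFAULT_START = datetime(2018, 5, 7, 0, 0, tzinfo=timezone.utc)


def _offset_deg(lat: float, dx_m: float, dy_m: float) -> tuple[float, float]:
    """Convert a local (east, north) meter offset to (dlat, dlon) degrees."""
    return dy_m / _M_PER_DEG_LAT, dx_m / (_M_PER_DEG_LAT * np.cos(np.radians(lat)))


@dataclass(frozen=True)
class GpsScenario:
    """A stationary-anchor trajectory with transits and a daily rhythm.

    ``circadian_strength`` interpolates between a perfectly 24-hour-periodic
    anchor sequence (1.0: each dwell slot of the day always maps to the same
    anchor) and a uniformly random anchor per dwell (0.0).
    """

    participant_id: str = "p01"
    anchors: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS
    circadian_strength: float = 1.0
    transit_speed_kmh: float = 20.0
    jitter_sd_m: float = 30.0
    dwell_hours: float = 2.0
    schedule: ScanSchedule = field(default_factory=lambda: STUDY_SCHEDULE)
    start: datetime = DEFAULT_START
    drop_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("need at least one anchor")
        if not 0.0 <= self.circadian_strength <= 1.0:
            raise ValueError("circadian_strength must be in [0, 1]")
        if not 0.0 <= self.drop_prob < 1.0:
            raise ValueError("drop_prob must be in [0, 1)")


def generate_gps(scenario: GpsScenario) -> list[GpsFix]:
    """Simulate GPS fixes at the scheduled scan instants.

    Each ``dwell_hours`` block is spent at one anchor: with probability
    ``circadian_strength`` the anchor is the deterministic daily template
    (dwell slot-of-day modulo the number of anchors), otherwise uniformly
    random.  When the anchor changes, the participant moves along the
    straight line between anchors at ``transit_speed_kmh`` from the start of
    the dwell; stationary fixes get isotropic Gaussian jitter of
    ``jitter_sd_m``.  Each scheduled fix is then dropped independently with
    ``drop_prob``, emulating missed scans.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    anchors = np.array(sc.anchors, dtype=float)
    k = len(anchors)
    if k > 1:
        dmin = min(haversine_m(tuple(anchors[i]), tuple(anchors[j]))
                   for i in range(k) for j in range(i + 1, k))
        if dmin < 2.0 * sc.jitter_sd_m:
            warnings.warn("anchors closer than 2 x jitter_sd; cluster recovery "
                          "is not guaranteed", stacklevel=2)

    instants = scan_instants(sc.schedule, sc.start)
    total_h = sc.schedule.total_duration.total_seconds() / 3600.0
    n_dwells = int(np.ceil(total_h / sc.dwell_hours))
    slots_per_day = max(1, int(round(24.0 / sc.dwell_hours)))

    # anchor index per dwell: daily template with probability s, else uniform.
    # The template visits each anchor in one contiguous block per day (home
    # overnight, work during the day, ...), giving a strong 24-h fundamental.
    slot_of_day = np.arange(n_dwells) % slots_per_day
    template = (slot_of_day * k) // slots_per_day
    follow = rng.random(n_dwells) < sc.circadian_strength
    random_anchor = rng.integers(0, k, size=n_dwells)
    dwell_anchor = np.where(follow, template, random_anchor)

    # transit window (hours from dwell start) when the anchor changes
    transit_until = np.zeros(n_dwells)
    for i in range(1, n_dwells):
        a, b = dwell_anchor[i - 1], dwell_anchor[i]
        if a != b:
            d_km = haversine_m(tuple(anchors[a]), tuple(anchors[b])) / 1000.0
            transit_until[i] = min(d_km / sc.transit_speed_kmh, sc.dwell_hours)

    keep = rng.random(len(instants)) >= sc.drop_prob
    fixes: list[GpsFix] = []
    for t, kept in zip(instants, keep):
        if not kept:
            continue
        h = (t - sc.start).total_seconds() / 3600.0
        i = min(int(h // sc.dwell_hours), n_dwells - 1)
        into = h - i * sc.dwell_hours
        cur = anchors[dwell_anchor[i]]
        if i > 0 and into < transit_until[i]:
            prev = anchors[dwell_anchor[i - 1]]
            frac = into / transit_until[i]
            lat = prev[0] + frac * (cur[0] - prev[0])
            lon = prev[1] + frac * (cur[1] - prev[1])
        else:
            dx, dy = rng.normal(0.0, sc.jitter_sd_m, size=2)
            dlat, dlon = _offset_deg(cur[0], dx, dy)
            lat, lon = cur[0] + dlat, cur[1] + dlon
        fixes.append(GpsFix(sc.participant_id, t, float(lat), float(lon)))
    return fixes


def office_hours_profile(peak: float = 2.0, base: float = 0.2,
                         start_h: int = 9, end_h: int = 17) -> np.ndarray:
    """Hour-of-day intensity peaking during office hours [start_h, end_h)."""
    lam = np.full(24, base)
    lam[start_h:end_h] = peak
    return lam


def home_hours_profile(high: float = 0.8, low: float = 0.2) -> np.ndarray:
    """Presence probability high outside working hours (a housemate's phone)."""
    p = np.full(24, high)
    p[9:17] = low
    return p


@dataclass(frozen=True)
class BluetoothScenario:
    """A known-device pool plus transient unknowns with hourly intensity."""

    participant_id: str = "p01"
    n_known: int = 3
    known_presence: np.ndarray = field(default_factory=home_hours_profile)
    unknown_rate: np.ndarray = field(default_factory=office_hours_profile)
    duration_days: int = 7
    interval_minutes: float = 5.0
    start: datetime = DEFAULT_START
    tz: str = DEFAULT_TZ
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.known_presence, float)
        lam = np.asarray(self.unknown_rate, float)
        if p.shape != (24,) or np.any(p < 0) or np.any(p > 1):
            raise ValueError("known_presence must be 24 probabilities in [0,1]")
        if lam.shape != (24,) or np.any(lam < 0):
            raise ValueError("unknown_rate must be 24 nonnegative intensities")


def generate_bluetooth(scenario: BluetoothScenario) -> list[BluetoothSighting]:
    """Simulate phone-class Bluetooth sightings scan by scan.

    At each scan, every known device is present independently with its
    hour-of-day probability (so known devices recur across many days), and
    a Poisson(lambda(hour)) number of brand-new transient device hashes
    appear, each seen only once (hence never promoted to known by the
    3-distinct-days rule).  All sightings carry the phone device class.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    tzinfo = get_tz(sc.tz)
    known_hashes = [hash_device_id(f"known-{i:03d}", "synthetic-known")
                    for i in range(sc.n_known)]
    presence = np.asarray(sc.known_presence, float)
    lam = np.asarray(sc.unknown_rate, float)

    n_scans = int(round(sc.duration_days * 24 * 60 / sc.interval_minutes))
    step = timedelta(minutes=sc.interval_minutes)
    sightings: list[BluetoothSighting] = []
    unknown_counter = 0
    for s in range(n_scans):
        t = sc.start + s * step
        h = t.astimezone(tzinfo).hour
        for dev in known_hashes:
            if rng.random() < presence[h]:
                sightings.append(BluetoothSighting(sc.participant_id, t, dev,
                                                   PHONE_MAJOR_CLASS))
        for _ in range(rng.poisson(lam[h])):
            dev = hash_device_id(f"unknown-{unknown_counter:08d}",
                                 "synthetic-unknown")
            unknown_counter += 1
            sightings.append(BluetoothSighting(sc.participant_id, t, dev,
                                               PHONE_MAJOR_CLASS))
    return sightings


#: Planted line from the study's fitted model: 21.3 h at rest, 18.8 h at 12 scans/h.
DEFAULT_LIFE_AT_REST_H = 21.3
DEFAULT_LIFE_COST_PER_RATE_H = (21.3 - 18.8) / 12.0   # hours lost per (scan/h)


@dataclass(frozen=True)
class BatteryScenario:
    """A fleet of discharging devices whose battery life falls with scan rate.

    Device d at scan rate r lives ``L_d - life_cost_per_rate_h * r`` hours
    on a full charge (so it discharges at 100 over that many hours, percent
    per hour), where the no-scanning life ``L_d`` is the fleet intercept
    plus Gaussian device jitter — the linear life-vs-rate model the analysis
    fits, planted exactly.  ``noise_sd`` adds independent Gaussian
    perturbation (%/h) to each device-week discharge rate, standing in for
    week-to-week variation in background consumption.  Phones recharge to
    100% once a day at ``charge_hour`` local time.
    """

    n_devices: int = 16
    intercept_life_h: float = DEFAULT_LIFE_AT_REST_H
    life_cost_per_rate_h: float = DEFAULT_LIFE_COST_PER_RATE_H
    device_jitter_sd_h: float = 4.0
    noise_sd: float = 0.0
    schedule: ScanSchedule = field(default_factory=lambda: STUDY_SCHEDULE)
    start: datetime = DEFAULT_START
    tz: str = DEFAULT_TZ
    charge_hour: int = 23
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intercept_life_h <= 0:
            raise ValueError("intercept life must be positive")
        if self.life_cost_per_rate_h < 0:
            raise ValueError("per-scan life cost must be nonnegative")
        max_rate = max((b.scans_per_hour for b in self.schedule.blocks),
                       default=0.0)
        if self.intercept_life_h - self.life_cost_per_rate_h * max_rate <= 0:
            raise ValueError("parameters imply non-positive battery life at "
                             "the fastest scan rate")


def generate_battery(scenario: BatteryScenario) -> list[BatterySample]:
    """Simulate battery levels for a device fleet at the scan instants.

    Levels start full, fall linearly at the device-and-block rate, clip at
    zero, and reset to 100% at the daily charge event (emitted as a
    charging-flagged sample so discharge segments split there).

    Raises
    ------
    ValueError
        If the drawn device parameters imply a non-positive battery life.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    tzinfo = get_tz(sc.tz)
    instants = scan_instants(sc.schedule, sc.start)
    end = sc.start + sc.schedule.total_duration

    # daily charge instants at charge_hour local time
    charges = []
    day = sc.start.astimezone(tzinfo).replace(hour=sc.charge_hour, minute=0,
                                              second=0, microsecond=0)
    while day < end.astimezone(tzinfo):
        if day > sc.start.astimezone(tzinfo):
            charges.append(day.astimezone(timezone.utc))
        day += timedelta(days=1)

    n_blocks = len(sc.schedule.blocks)
    samples: list[BatterySample] = []
    for d in range(sc.n_devices):
        life_d = sc.intercept_life_h + rng.normal(0.0, sc.device_jitter_sd_h)
        rates = np.empty(n_blocks)
        for b, blk in enumerate(sc.schedule.blocks):
            life_db = life_d - sc.life_cost_per_rate_h * blk.scans_per_hour
            if life_db <= 1.0:
                raise ValueError(
                    f"device {d} block {b}: implied life {life_db:.2f} h")
            rates[b] = 100.0 / life_db + rng.normal(0.0, sc.noise_sd)
            if rates[b] <= 0:
                raise ValueError(
                    f"device {d} block {b}: discharge rate {rates[b]:.3f} <= 0")

        pid = f"device{d:02d}"
        events = sorted([(t, False) for t in instants] + [(t, True) for t in charges])
        level, t_prev = 100.0, sc.start
        for t, is_charge in events:
            block = sc.schedule.block_of(sc.start, t)
            if block is None:
                continue
            dt_h = (t - t_prev).total_seconds() / 3600.0
            level = max(0.0, level - rates[block] * dt_h)
            t_prev = t
            if is_charge:
                level = 100.0
                samples.append(BatterySample(pid, t, level, True))
            elif level > 0.0:
                # a dead phone logs nothing until its next charge
                samples.append(BatterySample(pid, t, round(level, 4), False))
    return samples
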