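"""Battery-consumption model: discharge segments, per-rate life, robust fit.

The app's battery cost is identified by varying the scan rate weekly and
assuming consumption scales linearly with scans per hour.  From samples
taken while the phone was discharging, a mean discharge rate (% per hour)
is pooled per device and schedule block; extrapolating a full charge gives
an estimated battery life, ``100 / rate`` hours, per (device, scan-rate)
point.  A study-level line ``life = intercept + slope * scans_per_hour`` is
then fitted across devices by iteratively reweighted least squares with the
Tukey bisquare weight (tuning constant 4.685, MAD scale), which downweights
the outlying devices that dominate an ordinary fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .scheduling import ScanSchedule
from .sensor_io import BatterySample

#: Waking-day criterion: battery should last at least this long after a full charge.
WAKING_DAY_HOURS = 16.0

#: Bisquare tuning constant (95% efficiency under Gaussian errors).
BISQUARE_TUNING = 4.685


@dataclass(frozen=True)
class DischargeSegment:
    """A maximal run of non-charging, non-increasing battery samples."""

    participant_id: str
    samples: tuple[BatterySample, ...]

    @property
    def start(self) -> datetime:
        return self.samples[0].timestamp

    @property
    def end(self) -> datetime:
        return self.samples[-1].timestamp

    @property
    def duration_h(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0

    @property
    def drop_pct(self) -> float:
        return self.samples[0].level - self.samples[-1].level


@dataclass(frozen=True, slots=True)
class RatePoint:
    """Estimated battery life (hours) for one device at one scan rate."""

    device_id: str
    scans_per_hour: float
    life_hours: float


@dataclass(frozen=True)
class BatteryFit:
    """Robust linear fit of battery life against scan rate.

    ``intercept`` is the estimated life in hours with no scanning; ``slope``
    is hours of life lost per additional scan per hour (negative when
    scanning costs battery).
    """

    intercept: float
    slope: float
    weights: np.ndarray | None = None
    n_points: int = 0
    converged: bool = True
    intercept_se: float = float("nan")
    slope_se: float = float("nan")

    def predict(self, scans_per_hour) -> float | np.ndarray:
        return predict_life(self, scans_per_hour)

    def summary(self) -> str:
        lines = [
            "Robust battery-life fit (IRLS, Tukey bisquare c=4.685)",
            f"  n points:   {self.n_points}",
            f"  intercept:  {self.intercept:8.3f} h at 0 scans/h",
            f"  slope:      {self.slope:8.4f} h per (scan/h)",
            f"  converged:  {self.converged}",
        ]
        return "\n".join(lines)


def extract_discharge_segments(
    samples: Sequence[BatterySample], max_gap_minutes: float = 60.0
) -> list[DischargeSegment]:
    """Split time-sorted samples into maximal discharging runs.

    A segment ends at a charging sample, a gap longer than
    ``max_gap_minutes``, a level increase (e.g. a brief plug-in the charging
    flag missed), or a participant change.  Runs shorter than 2 samples are
    discarded.
    """
    segments: list[DischargeSegment] = []
    run: list[BatterySample] = []

    def flush():
        if len(run) >= 2:
            segments.append(DischargeSegment(run[0].participant_id, tuple(run)))
        run.clear()

    for s in samples:
        if s.is_charging:
            flush()
            continue
        if run:
            prev = run[-1]
            gap_min = (s.timestamp - prev.timestamp).total_seconds() / 60.0
            if (s.participant_id != prev.participant_id
                    or gap_min > max_gap_minutes or gap_min < 0):
                flush()
            elif s.level > prev.level:
                flush()
        run.append(s)
    flush()
    return segments


def battery_life_per_rate(
    segments: Sequence[DischargeSegment],
    schedule: ScanSchedule,
    start: datetime,
) -> list[RatePoint]:
    """Pool discharge rates per (device, schedule block) into life estimates.

    Each adjacent sample pair inside a segment is attributed to the schedule
    block containing it, so a segment spanning a block boundary contributes
    to both blocks rather than smearing one rate into the other.  Within a
    block the discharge rate is time-weighted: total level drop divided by
    total discharging time, so long segments count for more.  Life is the
    time to exhaust a full charge at that rate, ``100 / rate`` hours.
    Blocks with no usable discharge (no segments, zero duration or zero net
    drop) emit no point.
    """
    acc: dict[tuple[str, int], list[float]] = {}
    for seg in segments:
        for a, b in zip(seg.samples, seg.samples[1:]):
            block = schedule.block_of(start, b.timestamp)
            if block is None:
                continue
            dt_h = (b.timestamp - a.timestamp).total_seconds() / 3600.0
            if dt_h <= 0:
                continue
            drop_dur = acc.setdefault((seg.participant_id, block), [0.0, 0.0])
            drop_dur[0] += a.level - b.level
            drop_dur[1] += dt_h

    points: list[RatePoint] = []
    for (device, block), (drop, dur) in sorted(acc.items()):
        if dur <= 0 or drop <= 0:
            continue
        rate = drop / dur                        # % per hour
        points.append(RatePoint(device, schedule.blocks[block].scans_per_hour,
                                100.0 / rate))
    return points


def robust_fit_battery(points: Sequence[RatePoint]) -> BatteryFit:
    """Fit life ~ scans_per_hour by IRLS with Tukey bisquare weights.

    Tuning constant 4.685, scale from the normalized median absolute
    deviation of residuals, iterated to a relative coefficient change below
    1e-8 or 50 iterations.  Requires at least 3 points spanning at least 2
    distinct scan rates.
    """
    if len(points) < 3:
        raise ValueError("robust fit requires at least 3 rate points")
    x = np.array([p.scans_per_hour for p in points])
    y = np.array([p.life_hours for p in points])
    if np.unique(x).size < 2:
        raise ValueError("rate points are collinear: need >= 2 distinct scan rates")
    exog = sm.add_constant(x)
    model = sm.RLM(y, exog, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_TUNING))
    with warnings.catch_warnings():
        # zero scale just means the (weighted) fit is already exact
        warnings.filterwarnings("ignore", message="Estimated scale is 0.0")
        res = model.fit(scale_est="mad", conv="coefs", tol=1e-8, maxiter=50)
    n_iter = len(res.fit_history["params"])
    converged = n_iter < 50
    if not converged:
        warnings.warn("IRLS did not converge within 50 iterations", stacklevel=2)
    try:
        w = np.asarray(res.weights, dtype=float)
    except AttributeError:  # IRLS stopped early on a perfect fit
        w = np.ones(len(points))
    bse = np.asarray(res.bse, dtype=float)
    return BatteryFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        weights=w,
        n_points=len(points),
        converged=converged,
        intercept_se=float(bse[0]),
        slope_se=float(bse[1]),
    )


def predict_life(fit: BatteryFit, scans_per_hour) -> float | np.ndarray:
    """Predicted battery life (hours) at a scan rate from a fitted line."""
    pred = fit.intercept + fit.slope * np.asarray(scans_per_hour, dtype=float)
    if np.any(pred < 0):
        warnings.warn("predicted battery life is negative", stacklevel=2)
    return float(pred) if np.ndim(pred) == 0 else pred


def life_reduction(fit: BatteryFit, scans_per_hour: float) -> tuple[float, float]:
    """Battery-life cost of scanning at a rate, vs. not scanning at all.

    Returns (hours lost, percent of the no-scanning life lost).
    """
    base = predict_life(fit, 0.0)
    at_rate = predict_life(fit, scans_per_hour)
    hours = base - at_rate
    return hours, 100.0 * hours / base


def fraction_exceeding(
    points: Sequence[RatePoint], threshold_h: float = WAKING_DAY_HOURS,
    at_rate: float | None = None,
) -> float:
    """Share of devices whose life strictly exceeds a threshold at one rate.

    ``at_rate=None`` uses all points; otherwise only points at that scan
    rate.  Raises if no points qualify.
    """
    lives = [p.life_hours for p in points
             if at_rate is None or p.scans_per_hour == at_rate]
    if not lives:
        raise ValueError(f"no rate points at scans_per_hour={at_rate}")
    return sum(1 for v in lives if v > threshold_h) / len(lives)


def device_lines(points: Sequence[RatePoint]) -> dict[str, tuple[float, float]]:
    """Per-device OLS (intercept, slope) where a device has >= 2 rate points."""
    by_dev: dict[str, list[RatePoint]] = {}
    for p in points:
        by_dev.setdefault(p.device_id, []).append(p)
    out = {}
    for dev, pts in sorted(by_dev.items()):
        if len(pts) < 2:
            continue
        x = np.array([p.scans_per_hour for p in pts])
        y = np.array([p.life_hours for p in pts])
        if np.unique(x).size < 2:
            continue
        slope, intercept = np.polyfit(x, y, 1)
        out[dev] = (float(intercept), float(slope))
    return out
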