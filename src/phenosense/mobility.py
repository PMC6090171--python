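"""GPS mobility features: speed labeling, location clusters, circadian movement.

Each fix is labeled *stationary* or *transition* by its forward-difference
speed against a 1 km/h threshold.  Stationary fixes are partitioned into
location clusters by K-means, growing K from 1 until the farthest point in
every cluster lies within 500 m of its center.  Circadian movement (CM)
quantifies how strongly a participant's location sequence follows a 24-hour
rhythm: it is the base-10 logarithm of the spectral energy of the latitude
and longitude series inside the 24-hour frequency bin, obtained by
least-squares spectral analysis (Lomb-Scargle), which handles the irregular
sampling left by missed scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.signal import lombscargle
from sklearn.cluster import KMeans

from .sensor_io import GpsFix

EARTH_RADIUS_M = 6_371_000.0

#: Speed (km/h) separating stationary from transition fixes.
SPEED_THRESHOLD_KMH = 1.0

#: Radius criterion (m) for growing the number of location clusters.
CLUSTER_RADIUS_M = 500.0


class MotionState(str, Enum):
    STATIONARY = "stationary"
    TRANSITION = "transition"
    UNKNOWN = "unknown"


def haversine_m(a, b) -> float | np.ndarray:
    """Great-circle distance in meters between (lat, lon) points, R = 6371 km.

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lat1, lon1 = np.radians(np.asarray(a[0], float)), np.radians(np.asarray(a[1], float))
    lat2, lon2 = np.radians(np.asarray(b[0], float)), np.radians(np.asarray(b[1], float))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    return float(d) if np.ndim(d) == 0 else d


@dataclass(frozen=True, slots=True)
class LabeledFix:
    """A GPS fix with its estimated speed and stationary/transition label."""

    fix: GpsFix
    speed_kmh: float | None
    state: MotionState


def estimate_speeds(
    fixes: Sequence[GpsFix], max_gap_minutes: float = 30.0
) -> list[LabeledFix]:
    """Label fixes by forward-difference speed against the 1 km/h threshold.

    The speed of fix i is the haversine distance to fix i+1 divided by the
    time difference, assigned to fix i.  Pairs separated by more than
    ``max_gap_minutes`` (or with zero time difference) give no speed estimate
    and the fix is labeled ``unknown``, as is the last fix.  Stationary means
    strictly below the threshold; the boundary value itself is a transition.
    """
    out: list[LabeledFix] = []
    for i, fix in enumerate(fixes):
        if i == len(fixes) - 1:
            out.append(LabeledFix(fix, None, MotionState.UNKNOWN))
            continue
        nxt = fixes[i + 1]
        dt_h = (nxt.timestamp - fix.timestamp).total_seconds() / 3600.0
        if dt_h <= 0 or dt_h > max_gap_minutes / 60.0:
            out.append(LabeledFix(fix, None, MotionState.UNKNOWN))
            continue
        d_km = haversine_m((fix.latitude, fix.longitude),
                           (nxt.latitude, nxt.longitude)) / 1000.0
        speed = d_km / dt_h
        state = (MotionState.STATIONARY if speed < SPEED_THRESHOLD_KMH
                 else MotionState.TRANSITION)
        out.append(LabeledFix(fix, speed, state))
    return out


@dataclass(frozen=True)
class LocationClustering:
    """K-means partition of stationary fixes into location clusters."""

    k: int
    centers: np.ndarray          # (K, 2) lat, lon in degrees
    labels: np.ndarray           # cluster index per fix
    max_radius_m: float          # farthest point-to-own-center distance
    converged: bool              # radius criterion met before k_max


def _project_local(lat: np.ndarray, lon: np.ndarray):
    """Equirectangular projection to meters about the centroid (and inverse)."""
    lat0, lon0 = lat.mean(), lon.mean()
    m_per_deg = EARTH_RADIUS_M * np.pi / 180.0
    x = (lon - lon0) * m_per_deg * np.cos(np.radians(lat0))
    y = (lat - lat0) * m_per_deg

    def inverse(xy: np.ndarray) -> np.ndarray:
        lat_c = lat0 + xy[:, 1] / m_per_deg
        lon_c = lon0 + xy[:, 0] / (m_per_deg * np.cos(np.radians(lat0)))
        return np.column_stack([lat_c, lon_c])

    return np.column_stack([x, y]), inverse


def cluster_locations(
    stationary_fixes: Sequence[GpsFix],
    radius_m: float = CLUSTER_RADIUS_M,
    k_max: int = 50,
    seed: int = 0,
) -> LocationClustering:
    """Find the smallest K whose K-means solution meets the radius criterion.

    K is searched upward from 1; at each K a k-means++ fit (10 restarts,
    fixed seed) runs in a local equirectangular projection in meters, and the
    criterion — every stationary fix within ``radius_m`` of its own cluster
    center, measured by haversine on the final assignment — is checked.  If
    ``k_max`` is reached without satisfying it, the ``k_max`` solution is
    returned flagged non-convergent.
    """
    if len(stationary_fixes) == 0:
        raise ValueError("cluster_locations requires at least one stationary fix")
    lat = np.array([f.latitude for f in stationary_fixes])
    lon = np.array([f.longitude for f in stationary_fixes])
    xy, inverse = _project_local(lat, lon)

    best = None
    for k in range(1, min(k_max, len(stationary_fixes)) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(xy)
        centers = inverse(km.cluster_centers_)
        d = haversine_m((lat, lon),
                        (centers[km.labels_, 0], centers[km.labels_, 1]))
        max_r = float(np.max(d))
        best = LocationClustering(k, centers, km.labels_.copy(), max_r,
                                  converged=max_r < radius_m)
        if best.converged:
            return best
    warnings.warn(
        f"radius criterion {radius_m} m not met by K={best.k} (max radius "
        f"{best.max_radius_m:.0f} m); returning flagged result", stacklevel=2)
    return best


def ls_spectrum(
    times_h: np.ndarray, values: np.ndarray, freqs_cph: np.ndarray
) -> np.ndarray:
    """Least-squares spectral energy at each frequency (cycles/hour).

    For each frequency this equals the reduction in residual sum of squares
    achieved by fitting ``a*cos(2*pi*f*t) + b*sin(2*pi*f*t)`` to the
    mean-centered series by least squares — twice the classic Lomb-Scargle
    power, which scipy evaluates in O(n) per frequency.  Values are
    nonnegative; a constant series has zero energy everywhere.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("ls_spectrum requires at least 2 samples")
    y = y - y.mean()
    if np.allclose(y, 0.0):
        return np.zeros(len(np.atleast_1d(freqs_cph)))
    omega = 2.0 * np.pi * np.asarray(freqs_cph, dtype=float)
    power = 2.0 * lombscargle(t, y, omega)
    return np.maximum(power, 0.0)


def cm_frequency_grid(
    bin_hours: tuple[float, float] = (23.5, 24.5), n_freqs: int = 24
) -> np.ndarray:
    """Frequency grid (cycles/hour) covering the 24-hour period bin."""
    lo, hi = bin_hours
    return np.linspace(1.0 / hi, 1.0 / lo, n_freqs)


@dataclass(frozen=True, slots=True)
class CircadianMovement:
    """Spectral energy of latitude/longitude in the 24-h bin and its log."""

    energy_lat: float
    energy_lon: float
    cm: float                    # log10(energy_lat + energy_lon); NaN if zero
    low_confidence: bool         # series spans < 48 h


def circadian_movement(
    fixes: Sequence[GpsFix],
    bin_hours: tuple[float, float] = (23.5, 24.5),
    n_freqs: int = 24,
) -> CircadianMovement:
    """Circadian movement: log10 of the 24-h-bin energy of latitude + longitude.

    The Lomb-Scargle energy of the latitude and longitude series is summed
    over a grid of ``n_freqs`` frequencies spanning periods ``bin_hours``.
    A constant location has zero energy and CM is reported as missing (NaN)
    rather than -inf.  Series spanning less than 48 h are flagged
    low-confidence.  CM is invariant to translating the trajectory, since
    each series is mean-centered.
    """
    if len(fixes) < 2:
        raise ValueError("circadian_movement requires at least 2 fixes")
    t0 = fixes[0].timestamp
    t = np.array([(f.timestamp - t0).total_seconds() / 3600.0 for f in fixes])
    lat = np.array([f.latitude for f in fixes])
    lon = np.array([f.longitude for f in fixes])
    low_conf = (t[-1] - t[0]) < 48.0
    freqs = cm_frequency_grid(bin_hours, n_freqs)
    e_lat = float(np.sum(ls_spectrum(t, lat, freqs)))
    e_lon = float(np.sum(ls_spectrum(t, lon, freqs)))
    total = e_lat + e_lon
    if total <= 0.0:
        warnings.warn("zero 24-h spectral energy; CM undefined", stacklevel=2)
        cm = float("nan")
    else:
        cm = float(np.log10(total))
    return CircadianMovement(e_lat, e_lon, cm, low_conf)


def weekly_cm_reliability(cm_by_week: np.ndarray) -> float:
    """Cronbach alpha of per-week CM values (participants x weeks).

    alpha = K/(K-1) * (1 - sum of item variances / variance of row sums),
    with weeks as items; rows containing missing values are excluded
    casewise.  Requires at least 2 weeks and 2 complete rows and a nonzero
    total-score variance.
    """
    m = np.asarray(cm_by_week, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a participants x weeks matrix with >= 2 weeks")
    m = m[~np.isnan(m).any(axis=1)]
    if m.shape[0] < 2:
        raise ValueError("need >= 2 participants with complete data")
    k = m.shape[1]
    item_var = m.var(axis=0, ddof=1).sum()
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var / total_var))
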