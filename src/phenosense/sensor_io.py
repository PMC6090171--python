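"""Sensor record types, privacy transforms, and delimited-log readers/writers.

The pipeline ingests three kinds of per-participant sensor logs as RFC-4180
CSV with a header row, all timestamps UTC ISO-8601:

* ``gps.csv``        — ``participant_id,timestamp,latitude,longitude``
* ``bluetooth.csv``  — ``participant_id,timestamp,device_hash,device_class``
  (``device_class`` written as a hex literal, e.g. ``0x200``)
* ``battery.csv``    — ``participant_id,timestamp,level,is_charging``
  (``is_charging`` in ``{0,1}``)

Bluetooth device identifiers are never stored raw: they are replaced by a
salted SHA-256 digest on ingestion (:func:`hash_device_id`), mirroring the
on-handset hashing that protects participant privacy.  Hour-of-day and
calendar-day computations downstream use the participant's IANA timezone;
the default is Australia/Sydney.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Literal, Sequence
from zoneinfo import ZoneInfo

import pandas as pd

logger = logging.getLogger(__name__)

#: Default timezone for local-time computations (study ran in Australia).
DEFAULT_TZ = "Australia/Sydney"

#: Bluetooth Class-of-Device major-class mask (bits 8-12) and the Phone major class.
MAJOR_CLASS_MASK = 0x1F00
PHONE_MAJOR_CLASS = 0x200


@dataclass(frozen=True, slots=True)
class GpsFix:
    """One timestamped WGS84 coordinate — the atom of mobility analysis."""

    participant_id: str
    timestamp: datetime
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")


@dataclass(frozen=True, slots=True)
class BluetoothSighting:
    """One detection of a (hashed) nearby device during one scan."""

    participant_id: str
    scan_time: datetime
    device_hash: str
    device_class: int


@dataclass(frozen=True, slots=True)
class BatterySample:
    """One timestamped battery charge reading with charging state."""

    participant_id: str
    timestamp: datetime
    level: float
    is_charging: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 100.0:
            raise ValueError(f"battery level out of range: {self.level}")


def get_tz(tz_name: str = DEFAULT_TZ) -> ZoneInfo:
    """Resolve an IANA timezone name (DST-aware)."""
    return ZoneInfo(tz_name)


def hash_device_id(raw_identifier: str, salt: str = "") -> str:
    """Deterministic one-way digest of a device identifier.

    SHA-256 hex digest of ``salt + raw_identifier``; with an empty salt this
    is the plain SHA-256 of the identifier.  The same (identifier, salt) pair
    always yields the same digest, and the digest cannot be trivially
    inverted to recover the identifier.

    Raises
    ------
    ValueError
        If ``raw_identifier`` is empty.
    """
    if not raw_identifier:
        raise ValueError("raw_identifier must be non-empty")
    return hashlib.sha256((salt + raw_identifier).encode("utf-8")).hexdigest()


def is_phone_class(device_class: int) -> bool:
    """True if the Class-of-Device major class (bits 8-12) is Phone (0x200)."""
    return (device_class & MAJOR_CLASS_MASK) == PHONE_MAJOR_CLASS


def filter_phone_devices(
    sightings: Sequence[BluetoothSighting],
) -> list[BluetoothSighting]:
    """Retain only sightings of phone-class devices, preserving order.

    Devices whose Class-of-Device major-class field does not match the Phone
    major class 0x200 are removed, so that only other mobile phones enter the
    social-context analysis.  Idempotent.
    """
    return [s for s in sightings if is_phone_class(s.device_class)]


SensorKind = Literal["gps", "bluetooth", "battery"]

_SCHEMAS: dict[str, list[str]] = {
    "gps": ["participant_id", "timestamp", "latitude", "longitude"],
    "bluetooth": ["participant_id", "timestamp", "device_hash", "device_class"],
    "battery": ["participant_id", "timestamp", "level", "is_charging"],
}


def _parse_timestamp(value: str, line_no: int) -> datetime:
    try:
        ts = datetime.fromisoformat(str(value))
    except ValueError as exc:
        raise ValueError(f"line {line_no}: malformed timestamp {value!r}") from exc
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def read_sensor_log(
    path: str | Path, kind: SensorKind
) -> list[GpsFix] | list[BluetoothSighting] | list[BatterySample]:
    """Read one sensor log, returning typed records sorted by (participant, time).

    Exact-duplicate rows are dropped (count logged).  Unknown columns raise a
    warning and are ignored; a missing required column or a malformed field is
    an error naming the offending line (1-based, header is line 1).
    """
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown sensor kind: {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sensor log not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = _SCHEMAS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)
        df = df[required]

    n_before = len(df)
    df = df.drop_duplicates()
    n_dupes = n_before - len(df)
    if n_dupes:
        logger.info("%s: dropped %d exact-duplicate rows", path, n_dupes)

    records: list = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # +1 header, +1 one-based
        ts = _parse_timestamp(row["timestamp"], line_no)
        pid = str(row["participant_id"])
        try:
            if kind == "gps":
                records.append(
                    GpsFix(pid, ts, float(row["latitude"]), float(row["longitude"]))
                )
            elif kind == "bluetooth":
                records.append(
                    BluetoothSighting(pid, ts, str(row["device_hash"]),
                                      int(str(row["device_class"]), 0))
                )
            else:
                records.append(
                    BatterySample(pid, ts, float(row["level"]),
                                  bool(int(row["is_charging"])))
                )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {line_no}: {exc}") from exc

    time_attr = "scan_time" if kind == "bluetooth" else "timestamp"
    records.sort(key=lambda r: (r.participant_id, getattr(r, time_attr)))
    return records


def write_sensor_log(
    records: Iterable[GpsFix | BluetoothSighting | BatterySample],
    path: str | Path,
    kind: SensorKind,
) -> None:
    """Write typed records to CSV in the documented schema (round-trip safe)."""
    path = Path(path)
    rows = []
    for r in records:
        if kind == "gps":
            rows.append((r.participant_id, r.timestamp.isoformat(),
                         repr(float(r.latitude)), repr(float(r.longitude))))
        elif kind == "bluetooth":
            rows.append((r.participant_id, r.scan_time.isoformat(),
                         r.device_hash, f"0x{r.device_class:X}"))
        elif kind == "battery":
            rows.append((r.participant_id, r.timestamp.isoformat(),
                         repr(float(r.level)), int(r.is_charging)))
        else:
            raise ValueError(f"unknown sensor kind: {kind!r}")
    df = pd.DataFrame(rows, columns=_SCHEMAS[kind])
    df.to_csv(path, index=False)
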