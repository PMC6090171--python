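"""End-to-end orchestration: ingest logs, derive features, write reports.

A run is described by a :class:`RunConfig` (usually loaded from YAML) naming
the sensor logs, the scan schedule, the timezone and the per-stage
parameters.  :func:`run_pipeline` executes ingestion, completeness
accounting, mobility and social-context feature extraction and the battery
model, and writes one feature table row per participant plus per-week and
hourly side tables.  Runs are deterministic for fixed inputs and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import battery as battery_mod
from . import mobility, scheduling, sensor_io, social_context
from .scheduling import STUDY_SCHEDULE, ScanSchedule, ScheduleBlock

logger = logging.getLogger(__name__)


def proportion_pct(numerator: int, denominator: int) -> float:
    """A count as a percentage of a total (e.g. retention: 28 of 41 -> 68.3)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * numerator / denominator


def weekly_windows(
    records: Sequence, schedule: ScanSchedule, start: datetime
) -> tuple[dict[int, list], list]:
    """Partition records into schedule blocks by timestamp.

    Block boundaries belong to the later block; records outside every block
    go to an off-protocol bucket (returned second, with a logged count).
    """
    by_block: dict[int, list] = {i: [] for i in range(len(schedule.blocks))}
    off_protocol: list = []
    for r in records:
        t = getattr(r, "scan_time", None) or r.timestamp
        b = schedule.block_of(start, t)
        if b is None:
            off_protocol.append(r)
        else:
            by_block[b].append(r)
    if off_protocol:
        logger.info("%d records fell outside the schedule", len(off_protocol))
    return by_block, off_protocol


@dataclass
class RunConfig:
    """Everything a pipeline run needs; parameters default to the study's."""

    gps_path: Path | None = None
    bluetooth_path: Path | None = None
    battery_path: Path | None = None
    out_dir: Path = Path("phenosense_out")
    schedule: ScanSchedule = field(default_factory=lambda: STUDY_SCHEDULE)
    start: datetime = datetime(2018, 5, 7, tzinfo=timezone.utc)
    tz: str = sensor_io.DEFAULT_TZ
    # mobility
    radius_m: float = mobility.CLUSTER_RADIUS_M
    k_max: int = 50
    speed_max_gap_minutes: float = 30.0
    bin_hours: tuple[float, float] = (23.5, 24.5)
    n_freqs: int = 24
    seed: int = 0
    # social
    min_known_days: int = social_context.MIN_KNOWN_DAYS
    # battery
    battery_max_gap_minutes: float = 60.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def _path(key):
            return (base / raw[key]) if key in raw and raw[key] else None

        kwargs: dict = {}
        if "schedule" in raw:
            kwargs["schedule"] = ScanSchedule(
                [ScheduleBlock(b["days"], b["interval_minutes"])
                 for b in raw["schedule"]])
        if "start" in raw:
            start = raw["start"]
            if isinstance(start, str):
                start = datetime.fromisoformat(start)
            if start.tzinfo is None:
                start = start.replace(tzinfo=timezone.utc)
            kwargs["start"] = start
        for key in ("tz", "radius_m", "k_max", "speed_max_gap_minutes",
                    "n_freqs", "seed", "min_known_days",
                    "battery_max_gap_minutes"):
            if key in raw:
                kwargs[key] = raw[key]
        if "bin_hours" in raw:
            kwargs["bin_hours"] = tuple(raw["bin_hours"])
        return cls(
            gps_path=_path("gps"),
            bluetooth_path=_path("bluetooth"),
            battery_path=_path("battery"),
            out_dir=base / raw.get("out_dir", "phenosense_out"),
            **kwargs,
        )

    def echo(self) -> dict:
        """Parameter echo for the run log."""
        return {
            "schedule": [{"days": b.days, "interval_minutes": b.interval_minutes}
                         for b in self.schedule.blocks],
            "start": self.start.isoformat(),
            "tz": self.tz,
            "radius_m": self.radius_m,
            "k_max": self.k_max,
            "speed_max_gap_minutes": self.speed_max_gap_minutes,
            "bin_hours": list(self.bin_hours),
            "n_freqs": self.n_freqs,
            "seed": self.seed,
            "min_known_days": self.min_known_days,
            "battery_max_gap_minutes": self.battery_max_gap_minutes,
        }


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run every configured stage and write reports to ``config.out_dir``.

    Outputs: ``features.csv`` (one row per participant), ``cm_weekly.csv``,
    ``profile.csv``, ``completeness.csv``, ``battery_points.csv``,
    ``battery_fit.json`` and ``run_log.json``.  Any stage failure aborts
    with the stage name, removing partial outputs of this run.

    Returns the feature table.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format="%.6g")
        written.append(p)

    try:
        return _run(config, out, _write_csv, written)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, StageError):
            raise
        raise StageError("setup", exc) from exc


def _run(config: RunConfig, out: Path, _write_csv, written: list[Path]) -> pd.DataFrame:
    counts: dict[str, int] = {}

    # --- ingest -----------------------------------------------------------
    try:
        gps = (sensor_io.read_sensor_log(config.gps_path, "gps")
               if config.gps_path else [])
        bt = (sensor_io.read_sensor_log(config.bluetooth_path, "bluetooth")
              if config.bluetooth_path else [])
        bt = sensor_io.filter_phone_devices(bt)
        batt = (sensor_io.read_sensor_log(config.battery_path, "battery")
                if config.battery_path else [])
    except Exception as exc:
        raise StageError("ingest", exc) from exc
    counts.update(n_gps=len(gps), n_bluetooth=len(bt), n_battery=len(batt))

    participants = sorted({r.participant_id for r in gps}
                          | {r.participant_id for r in bt})

    # --- completeness (Bluetooth-or-GPS against the joint schedule) -------
    try:
        comp_rows = []
        for pid in participants:
            rep = scheduling.completeness(
                [r for r in gps if r.participant_id == pid]
                + [r for r in bt if r.participant_id == pid],
                config.schedule, config.start, pid)
            comp_rows.append((pid, rep.scheduled, rep.collected, rep.pct))
        comp_df = pd.DataFrame(
            comp_rows, columns=["participant_id", "scheduled", "collected", "pct"])
        _write_csv(comp_df, "completeness.csv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("completeness", exc) from exc

    # --- mobility ---------------------------------------------------------
    try:
        feat_rows, cm_rows = [], []
        for pid in participants:
            fixes = [r for r in gps if r.participant_id == pid]
            row: dict = {"participant_id": pid, "n_fixes": len(fixes)}
            if len(fixes) >= 2:
                labeled = mobility.estimate_speeds(
                    fixes, config.speed_max_gap_minutes)
                stationary = [lf.fix for lf in labeled
                              if lf.state is mobility.MotionState.STATIONARY]
                row["n_stationary"] = len(stationary)
                if stationary:
                    clus = mobility.cluster_locations(
                        stationary, config.radius_m, config.k_max, config.seed)
                    row["n_clusters"] = clus.k
                    row["max_radius_m"] = clus.max_radius_m
                    row["cluster_converged"] = clus.converged
                cm_all = mobility.circadian_movement(
                    fixes, config.bin_hours, config.n_freqs)
                row["cm"] = cm_all.cm
                row["cm_low_confidence"] = cm_all.low_confidence
                by_block, _ = weekly_windows(fixes, config.schedule, config.start)
                for b, recs in by_block.items():
                    cm_w = (mobility.circadian_movement(
                        recs, config.bin_hours, config.n_freqs).cm
                        if len(recs) >= 2 else float("nan"))
                    cm_rows.append((pid, b, len(recs), cm_w))
            feat_rows.append(row)
        cm_df = pd.DataFrame(cm_rows,
                             columns=["participant_id", "block", "n_fixes", "cm"])
        _write_csv(cm_df, "cm_weekly.csv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("mobility", exc) from exc

    # --- social context ---------------------------------------------------
    try:
        prof_rows = []
        for pid in participants:
            sightings = [s for s in bt if s.participant_id == pid]
            if not sightings:
                continue
            catalog = social_context.classify_known_devices(
                sightings, config.min_known_days, config.tz)
            prof = social_context.hourly_context_profile(
                sightings, catalog, config.tz)
            prof = prof.reset_index()
            prof.insert(0, "participant_id", pid)
            prof_rows.append(prof)
            for row in feat_rows:
                if row["participant_id"] == pid:
                    row["n_known_devices"] = len(catalog.known)
                    row["n_unknown_devices"] = len(catalog.unknown)
        if prof_rows:
            _write_csv(pd.concat(prof_rows, ignore_index=True), "profile.csv")
        else:
            _write_csv(pd.DataFrame(
                columns=["participant_id", "hour", "mean_known",
                         "mean_unknown", "n_scans"]), "profile.csv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("social_context", exc) from exc

    # --- battery ----------------------------------------------------------
    try:
        segments = battery_mod.extract_discharge_segments(
            batt, config.battery_max_gap_minutes)
        points = battery_mod.battery_life_per_rate(
            segments, config.schedule, config.start)
        pts_df = pd.DataFrame(
            [(p.device_id, p.scans_per_hour, p.life_hours) for p in points],
            columns=["device_id", "scans_per_hour", "life_hours"])
        _write_csv(pts_df, "battery_points.csv")
        fit_payload: dict = {"n_points": len(points)}
        if len(points) >= 3 and len({p.scans_per_hour for p in points}) >= 2:
            fit = battery_mod.robust_fit_battery(points)
            fit_payload.update(
                intercept_hours=fit.intercept,
                slope_hours_per_scanrate=fit.slope,
                converged=fit.converged,
            )
        fit_path = out / "battery_fit.json"
        fit_path.write_text(json.dumps(fit_payload, indent=2, sort_keys=True))
        written.append(fit_path)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("battery", exc) from exc

    # --- assemble ---------------------------------------------------------
    try:
        cols = ["participant_id", "n_fixes", "n_stationary", "n_clusters",
                "max_radius_m", "cluster_converged", "cm", "cm_low_confidence",
                "n_known_devices", "n_unknown_devices"]
        feat_df = pd.DataFrame(feat_rows).reindex(columns=cols)
        feat_df = feat_df.merge(comp_df[["participant_id", "pct"]]
                                .rename(columns={"pct": "completeness_pct"}),
                                on="participant_id", how="left")
        _write_csv(feat_df, "features.csv")

        log = {
            "config": config.echo(),
            "counts": counts,
            "n_participants": len(participants),
        }
        # weekly CM reliability across participants, when estimable
        if len(participants) >= 2 and len(config.schedule.blocks) >= 2:
            mat = (cm_df.pivot(index="participant_id", columns="block",
                               values="cm").to_numpy())
            try:
                log["weekly_cm_cronbach_alpha"] = mobility.weekly_cm_reliability(mat)
            except ValueError:
                log["weekly_cm_cronbach_alpha"] = None
        log_path = out / "run_log.json"
        log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
        written.append(log_path)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("assemble", exc) from exc

    return feat_df
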