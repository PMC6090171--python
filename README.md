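# phenosense

A pipeline for **passive mobile-sensing studies**: it turns raw phone-sensor
logs — GPS fixes, Bluetooth sightings and battery samples collected on a
fixed scan schedule — into the behavioral features used in digital
phenotyping, together with the data-quality accounting such studies need.
It is written for researchers running feasibility or mental-health sensing
studies who want the feature extraction, completeness bookkeeping and
battery-cost estimation to be reproducible and testable rather than ad-hoc
scripts.

## What it computes

**Mobility (GPS).** Each fix is labeled *stationary* or *transition* by its
forward-difference speed against a 1 km/h threshold. Stationary fixes are
partitioned into **location clusters** by K-means, increasing K from 1 until
the farthest point in every cluster lies within 500 m of its center.
**Circadian movement** measures how strongly the location sequence follows a
24-hour rhythm:

    CM = log10( E_lat + E_lon ),

where `E` is the least-squares (Lomb–Scargle) spectral energy of the
latitude and longitude series summed over the frequency bin covering periods
of 23.5–24.5 h. The Lomb–Scargle periodogram is the right spectral tool
here because missed scans leave the series irregularly sampled. Week-to-week
consistency of CM is summarized by Cronbach alpha.

**Social context (Bluetooth).** Sightings are filtered to the phone
Class-of-Device major class (0x200) and device identifiers are salted
SHA-256 digests. A device is **known** to a participant once seen on ≥ 3
distinct local calendar days; others are **unknown**. The mean number of
distinct known and unknown devices per scan, by local hour of day, forms a
24-point social-context profile.

**Completeness.** Against a scan schedule of weekly blocks (the default
protocol scans every 3, 4, 5 and 8 minutes, one week each — 9156 scheduled
scans in four weeks), completeness is the percentage of scheduled instants
with at least one collected record.

**Battery.** From samples taken while discharging, a mean discharge rate
(%/h) is pooled per device and schedule block and extrapolated to a battery
life `100/rate` hours. Across devices, life is regressed on scans per hour
by iteratively reweighted least squares with the Tukey bisquare weight
(c = 4.685), which keeps outlying devices from dominating:

    life = β₀ + β₁ · scans_per_hour + ε.

**Synthetic data.** Because real GPS traces re-identify participants,
`phenosense.synthetic` generates trajectories, Bluetooth logs and battery
series with planted ground truth (anchor count, circadian strength,
hour-of-day intensities, the linear battery model), so every stage is tested
by parameter recovery.

## Worked example

```python
from phenosense import *
from phenosense.mobility import MotionState
from phenosense.synthetic import (BatteryScenario, GpsScenario,
                                  generate_battery, generate_gps)

# four-week trajectory, 45% of scans dropped (a typical Android device)
sc = GpsScenario(seed=42, drop_prob=0.45)
fixes = generate_gps(sc)
rep = completeness(fixes, STUDY_SCHEDULE, sc.start, "p01")
print(f"completeness: {rep.collected}/{rep.scheduled} = {rep.pct:.1f}%")

stationary = [lf.fix for lf in estimate_speeds(fixes)
              if lf.state is MotionState.STATIONARY]
clus = cluster_locations(stationary, seed=0)
print(f"location clusters: K={clus.k} (max radius {clus.max_radius_m:.0f} m)")
print(f"circadian movement: {circadian_movement(fixes).cm:.2f}")

bsc = BatteryScenario(seed=42, noise_sd=0.2)   # 16-device fleet
points = battery_life_per_rate(
    extract_discharge_segments(generate_battery(bsc)), bsc.schedule, bsc.start)
fit = robust_fit_battery(points)
print(fit.summary())
h, p = life_reduction(fit, 12.0)
print(f"reduction vs no scanning: {h:.1f} h ({p:.0f}%)")
```

prints

```
completeness: 4997/9156 = 54.6%
location clusters: K=5 (max radius 216 m)
circadian movement: 0.61
Robust battery-life fit (IRLS, Tukey bisquare c=4.685)
  n points:   64
  intercept:    21.506 h at 0 scans/h
  slope:       -0.2094 h per (scan/h)
  converged:  True
reduction vs no scanning: 2.5 h (12%)
```

Half the scheduled scans arrived (the generator dropped 45% of them); the
five planted anchor locations were recovered as five clusters all tighter
than 500 m; the trajectory's strong daily rhythm gives a positive CM; and
the fleet's fitted line says a phone lasting ~21.5 h idle loses ~0.21 h of
life per extra scan per hour — scanning every 5 minutes (12 scans/h) costs
about 2.5 h (12%) of battery life.

There is also a CLI: `phenosense simulate`, `phenosense run --config
run.yaml`, and per-stage subcommands (`mobility`, `social`, `battery`,
`completeness`). A run writes `features.csv` (one row per participant),
`cm_weekly.csv`, `profile.csv`, `completeness.csv`, `battery_points.csv`,
`battery_fit.json` and a `run_log.json` echoing all parameters.

## Layout

| module | contents |
| --- | --- |
| `phenosense.sensor_io` | record types, CSV readers/writers, device hashing, phone-class filter |
| `phenosense.scheduling` | scan schedules, scheduled counts, completeness |
| `phenosense.mobility` | speeds, location clustering, Lomb–Scargle spectrum, CM, Cronbach alpha |
| `phenosense.social_context` | known/unknown device catalog, hourly profiles |
| `phenosense.battery` | discharge segments, per-rate life, robust fit, predictions |
| `phenosense.synthetic` | scenario dataclasses and the three generators |
| `phenosense.pipeline` / `phenosense.cli` | run configuration, orchestration, console script |

See `docs/methods.md` for the modelling choices, defaults and limitations.
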