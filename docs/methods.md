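# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices a maintainer would otherwise have to reverse
engineer from the code.

## Scan schedule and completeness

The protocol is a list of blocks `(days, interval_minutes)`; the default is
one week each at 3, 4, 5 and 8 minutes, i.e. 20, 15, 12 and 7.5 scans per
hour, which schedules (20+15+12+7.5)×24×7 = 9156 scans over four weeks.
Fractional scans-per-hour are kept exact per block and rounded only on the
final sum.

A scheduled instant counts as *collected* when any record for the
participant falls within half the block's inter-scan interval of it. Phone
clocks jitter and upload timestamps are not guaranteed to sit exactly on
the schedule, so exact matching would undercount; the half-interval window
is the widest tolerance that cannot double-count one record interval. By
default Bluetooth and GPS records are pooled into one accounting (they ride
the same scan trigger); per-sensor accounting is a matter of passing only
one record kind.

## Mobility

**Speeds.** Forward differences: `speed_i = d(fix_i, fix_{i+1}) / Δt`,
assigned to the earlier fix; distance is haversine with R = 6 371 000 m.
Pairs with Δt = 0 or Δt > 30 min (default `max_gap`) yield no estimate —
differencing across an outage would produce a spuriously low speed and
mislabel a genuinely moving participant as stationary. Stationary is
*strictly* below 1 km/h; the boundary value counts as movement.

**Location clusters.** K is grown from 1; each K is fitted by k-means++
with 10 restarts and a fixed seed (ties broken by inertia inside
scikit-learn), and accepted as soon as every stationary fix lies within
500 m (haversine) of its own center. K-means runs in a local
equirectangular projection in meters centred on the data: at Australian
latitudes a degree of longitude is ~92 km versus ~111 km for latitude, so
clustering raw degrees would stretch the east–west axis by ~20%. The
radius check, however, is done with haversine on the final assignment, so
the radius criterion does not inherit projection error. `k_max`
defaults to 50 — participant cluster counts in field data run up to ~30,
so the cap leaves headroom while still terminating on pathological input
(the capped result is returned flagged, never silently).

**Circadian movement.** For irregularly sampled series the classic
periodogram is replaced by least-squares spectral analysis: at frequency f
the energy is the reduction in residual sum of squares from fitting
`a·cos(2πft) + b·sin(2πft)` to the mean-centred series. This equals exactly
2× the Lomb–Scargle power, and the implementation uses
`scipy.signal.lombscargle` with that factor (verified against the direct
per-frequency fit to machine precision in the tests). The 24-hour bin is a
grid of 24 equally spaced frequencies spanning periods 23.5–24.5 h — the
bin edges are a configurable knob (`bin_hours`) since the convention varies
across studies; energy is summed over the grid separately for latitude and
longitude and `CM = log10(E_lat + E_lon)` (base 10). Zero total energy
(constant location) gives a *missing* CM rather than −∞ or an epsilon
floor: inventing a floor would manufacture a spurious lower tail in any
downstream regression. Series spanning under 48 h cannot resolve a 24-h
period and are flagged low-confidence. Mean-centring makes CM invariant to
translating the trajectory.

Clustering defaults to the whole study window and CM is additionally
computed per schedule block (week), since week-by-rate is the design cell;
both windows are exposed.

**Reliability.** Week-to-week consistency of CM is Cronbach alpha with
weeks as items, `α = K/(K−1)·(1 − Σ item variances / variance of row
sums)`, casewise deletion of incomplete rows, sample variances (ddof 1).
The implementation is the five-line definition; tests cross-check it
against pingouin.

## Social context

Bluetooth sightings are first filtered to Class-of-Device major class
Phone: the major class occupies bits 8–12, so the test is
`(device_class & 0x1F00) == 0x200`, which keeps sub-classed phone codes
such as 0x20C (smartphone). Identifiers are salted SHA-256 digests; the
salt is configuration, not a guess, since deployments differ in whether the
handset salts.

A *day* is a local calendar day in the participant's IANA timezone
(default `Australia/Sydney`): UTC days would split evenings at UTC+10/+11
across two dates and systematically inflate distinct-day counts. Known
means ≥ 3 distinct days; the catalog is per participant — in an open
population, device familiarity does not transfer between participants.

Hourly profiles average the number of *distinct* known and unknown hashes
per scan over the scans whose local start time falls in each hour. A scan
that detected nothing leaves no trace in a sightings log, so the default
denominator is the set of scan times present in the log; callers who know
the full schedule can pass `scan_times` to include empty scans. The
per-hour scan count is always reported so either denominator is auditable.

## Battery

Discharge segments are maximal runs of non-charging samples with no gap
over 60 min and non-increasing level; a level uptick splits the run (a
plug-in the charging flag missed). Per device and block, the discharge
rate is time-weighted — total drop over total duration across the block's
pairs, with each adjacent sample pair attributed to the block containing
it, so a segment spanning a rate change does not smear one week's rate
into the next. Life is `100/rate`: the time to exhaust a full charge at
constant rate, the linearization the study design implies.

The fleet model `life = β₀ + β₁·r` is fitted by IRLS with the Tukey
bisquare weight, tuning constant 4.685 (95% Gaussian efficiency — the
standard choice when the constant is unstated), scale re-estimated each
iteration by the normalized MAD of residuals, convergence on relative
coefficient change < 1e−8, cap 50 iterations. statsmodels' RLM provides
the machinery; an exactly collinear (zero-residual) input short-circuits to
the perfect fit with unit weights. Coefficient standard errors from the
robust fit are carried on the result. Per-device OLS lines are available
where a device has ≥ 2 rate points.

## Synthetic generators

All three generators are pure functions of a frozen scenario dataclass
(seed included).

*GPS.* Time is divided into 2-h dwells; with probability `s` (circadian
strength) a dwell follows a deterministic daily template — each of the K
anchors held for one contiguous block of the day, giving the strong 24-h
fundamental a commuter's day has — otherwise the anchor is uniform random.
`s` is therefore monotone in expected 24-h spectral energy, with `s = 1` a
perfectly repeating day and `s = 0` structureless. Anchor changes move the
participant along the straight line between anchors at 20 km/h; stationary
fixes get isotropic Gaussian jitter (30 m, about urban GPS accuracy);
scans are dropped i.i.d. Bernoulli. The default five anchors sit ≥ 2 km
apart around Sydney so the 500-m criterion identifies them
unambiguously. Not emulated: accuracy-dependent noise, urban canyon
multipath, gap bursts correlated with place (missingness is independent),
or realistic road routing — so passing recovery tests show the estimators
invert this generative model, not that they are robust to every field
pathology.

*Bluetooth.* Known devices appear per-scan with an hour-of-day presence
probability (default high outside 9–17, a household member); unknown
devices are fresh hashes drawn Poisson(λ(hour)) per scan with λ peaking
9–17 (office hours), drawn from a disjoint hash namespace so the ≥ 3-day
rule can never accidentally promote one. Each sighting carries the phone
class.

*Battery.* Device d at scan rate r lives `L_d − c·r` hours on a full
charge, with `L_d` Gaussian around the fleet intercept (SD 4 h) — i.e. the
linear life-vs-rate model the analysis fits is planted exactly, with
defaults inverted from the fitted line (21.3 h at rest, 18.8 h at 12
scans/h, so c = 2.5/12 h per scan/h). `noise_sd` perturbs each
device-week's discharge rate (background-usage variation between weeks),
not individual samples: per-sample noise on a monotone level trace would
make the uptick-splitting rule censor negative increments and bias rates
upward, a measurement artifact rather than the consumption process being
modelled. Phones recharge instantly to 100% at 23:00 local daily so
discharge spans waking hours; a dead phone logs nothing until its next
charge, as in reality — which also means the observed-pair rate estimator
stays unbiased when a battery expires before the nightly charge.

## Pipeline

Records partition into schedule blocks by timestamp with boundaries going
to the later block; out-of-window records go to an off-protocol bucket and
counts reconcile exactly. Runs are deterministic for fixed inputs and seed
(fixed k-means seed, `%.6g` float formatting in CSVs); a stage failure
aborts with the stage name and removes that run's partial outputs.

## Problem sizes in the checks

The automated checks run the generators at one-week windows at the
8-minute rate for mobility recovery (≈1260 fixes per trajectory, 20 seeds),
the full four-week schedule for completeness (n = 9156) and the battery
fleet (16 devices × 4 rates), and a four-interval × two-day schedule for
the end-to-end determinism run — sizes at which every planted parameter is
comfortably identifiable while the whole suite stays fast.

## Known limitations

- Completeness assumes the configured schedule was actually in force; it
  cannot detect a device that silently rescheduled scans.
- CM on under two days of data is flagged, not refused; interpret flagged
  values cautiously.
- The battery model is linear in scan rate by assumption; screen time,
  radio conditions and OS throttling are absorbed into device jitter and
  week noise, not modelled.
- No GPS accuracy field is modelled or filtered on; if a deployment logs
  accuracy radii, filtering should happen upstream of ingestion.
- Cross-participant device linkage is deliberately out of scope.
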