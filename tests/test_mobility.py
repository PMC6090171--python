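import numpy as np
import pytest

from phenosense import (
    circadian_movement,
    cluster_locations,
    estimate_speeds,
    haversine_m,
    ls_spectrum,
    weekly_cm_reliability,
)
from phenosense.mobility import MotionState, cm_frequency_grid

from conftest import make_fixes


class TestHaversine:
    def test_zero_distance(self):
        assert haversine_m((-33.89, 151.21), (-33.89, 151.21)) == 0.0

    def test_hundredth_degree_of_latitude(self):
        # closed form at R = 6371 km: 0.01 * pi/180 * 6 371 000 m
        assert haversine_m((0, 0), (0.01, 0)) == pytest.approx(1111.9493, abs=0.01)

    def test_symmetric(self):
        a, b = (-33.89, 151.21), (-33.87, 151.25)
        assert haversine_m(a, b) == pytest.approx(haversine_m(b, a))


class TestEstimateSpeeds:
    def test_forward_difference_speed_and_transition(self):
        fixes = make_fixes([(0.0, 0.0), (0.01, 0.0)], step_minutes=5)
        labeled = estimate_speeds(fixes)
        # 1111.95 m in 5 min = 13.34 km/h, above the 1 km/h threshold
        assert labeled[0].speed_kmh == pytest.approx(13.343, abs=0.01)
        assert labeled[0].state is MotionState.TRANSITION
        assert labeled[1].state is MotionState.UNKNOWN

    def test_identical_coordinates_stationary(self):
        labeled = estimate_speeds(make_fixes([(0.0, 0.0)] * 3, step_minutes=5))
        assert labeled[0].speed_kmh == 0.0
        assert labeled[0].state is MotionState.STATIONARY

    def test_large_gap_gives_unknown(self):
        fixes = make_fixes([(0.0, 0.0), (0.0, 0.0)], step_minutes=90)
        labeled = estimate_speeds(fixes, max_gap_minutes=30)
        assert labeled[0].state is MotionState.UNKNOWN

    def test_single_fix_unknown(self):
        labeled = estimate_speeds(make_fixes([(0.0, 0.0)]))
        assert [lf.state for lf in labeled] == [MotionState.UNKNOWN]

    def test_time_rescaling_rescales_speed(self):
        coords = [(0.0, 0.0), (0.005, 0.0), (0.005, 0.005)]
        fast = estimate_speeds(make_fixes(coords, step_minutes=5))
        slow = estimate_speeds(make_fixes(coords, step_minutes=10))
        for f, s in zip(fast[:-1], slow[:-1]):
            assert f.speed_kmh == pytest.approx(2 * s.speed_kmh)


class TestClusterLocations:
    def test_single_tight_cloud_is_one_cluster(self):
        rng = np.random.default_rng(0)
        # jitter well under 100 m around one center
        coords = [(-33.89 + dy, 151.21 + dx)
                  for dx, dy in rng.normal(0, 0.0003, size=(50, 2))]
        clus = cluster_locations(make_fixes(coords), seed=0)
        assert clus.k == 1 and clus.converged

    def test_two_groups_2km_apart_need_two_clusters(self):
        rng = np.random.default_rng(1)
        a = [(-33.89 + dy, 151.21 + dx)
             for dx, dy in rng.normal(0, 0.0005, size=(30, 2))]
        b = [(-33.872 + dy, 151.21 + dx)
             for dx, dy in rng.normal(0, 0.0005, size=(30, 2))]
        fixes = make_fixes(a + b)
        clus = cluster_locations(fixes, seed=0)
        # oracle: one cluster cannot meet the 500 m criterion (groups ~2 km
        # apart, so some point is >= ~1 km from any single center), two can
        lat = np.array([f.latitude for f in fixes])
        lon = np.array([f.longitude for f in fixes])
        center = (lat.mean(), lon.mean())
        worst_k1 = max(haversine_m((la, lo), center) for la, lo in zip(lat, lon))
        assert worst_k1 >= 500.0
        assert clus.k == 2
        assert clus.max_radius_m < 500.0

    def test_decreasing_radius_never_decreases_k(self):
        rng = np.random.default_rng(2)
        groups = []
        for base in [(-33.89, 151.21), (-33.87, 151.21), (-33.89, 151.24)]:
            groups += [(base[0] + dy, base[1] + dx)
                       for dx, dy in rng.normal(0, 0.002, size=(40, 2))]
        fixes = make_fixes(groups)
        ks = [cluster_locations(fixes, radius_m=r, seed=0).k
              for r in (2000.0, 1000.0, 500.0, 250.0)]
        assert ks == sorted(ks)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_locations([])

    def test_k_max_reached_is_flagged(self):
        rng = np.random.default_rng(3)
        coords = [(-33.5 + dy, 151.0 + dx)
                  for dx, dy in rng.uniform(-0.2, 0.2, size=(60, 2))]
        with pytest.warns(UserWarning, match="criterion"):
            clus = cluster_locations(make_fixes(coords), k_max=2, seed=0)
        assert clus.k == 2 and not clus.converged


class TestLsSpectrum:
    def test_peak_at_24h_for_daily_sinusoid(self):
        t = np.arange(0, 24 * 7, 0.5)
        y = np.sin(2 * np.pi * t / 24.0)
        freqs = np.array([1 / 48, 1 / 24, 1 / 12, 1 / 6])
        p = ls_spectrum(t, y, freqs)
        assert np.argmax(p) == 1

    def test_matches_direct_least_squares_fit(self):
        rng = np.random.default_rng(4)
        t = np.sort(rng.uniform(0, 24 * 7, 300))
        y = rng.normal(size=t.size)
        freqs = rng.uniform(0.005, 0.5, size=10)
        p = ls_spectrum(t, y, freqs)
        yc = y - y.mean()
        for f, power in zip(freqs, p):
            X = np.column_stack([np.cos(2 * np.pi * f * t),
                                 np.sin(2 * np.pi * f * t)])
            beta, *_ = np.linalg.lstsq(X, yc, rcond=None)
            drss = (yc ** 2).sum() - ((yc - X @ beta) ** 2).sum()
            assert power == pytest.approx(drss, rel=1e-8)

    def test_peak_survives_random_deletion(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 24 * 7, 0.25)
        keep = rng.random(t.size) < 0.5
        t = t[keep]
        y = np.sin(2 * np.pi * t / 24.0) + rng.normal(0, 0.1, t.size)
        freqs = np.concatenate([[1 / 24], rng.uniform(1 / 20, 1 / 4, 30)])
        p = ls_spectrum(t, y, freqs)
        assert np.argmax(p) == 0

    def test_constant_series_zero_power(self):
        t = np.arange(10.0)
        p = ls_spectrum(t, np.full(10, 3.7), np.array([0.1, 0.2]))
        assert np.all(p == 0.0)


class TestCircadianMovement:
    @staticmethod
    def _daily_fixes(noise=1e-5, shuffle=False, seed=0):
        rng = np.random.default_rng(seed)
        hours = np.arange(0, 24 * 7, 0.5)
        lat = -33.89 + 0.01 * np.sin(2 * np.pi * hours / 24)
        lon = 151.21 + 0.01 * np.cos(2 * np.pi * hours / 24)
        lat = lat + rng.normal(0, noise, hours.size)
        lon = lon + rng.normal(0, noise, hours.size)
        if shuffle:
            perm = rng.permutation(hours.size)
            lat, lon = lat[perm], lon[perm]
        return make_fixes(list(zip(lat, lon)), step_minutes=30)

    def test_sinusoid_beats_shuffled(self):
        cm_daily = circadian_movement(self._daily_fixes()).cm
        cm_shuffled = circadian_movement(self._daily_fixes(shuffle=True)).cm
        assert cm_daily > cm_shuffled

    def test_constant_location_is_missing(self):
        with pytest.warns(UserWarning, match="zero"):
            result = circadian_movement(make_fixes([(-33.89, 151.21)] * 10))
        assert np.isnan(result.cm)

    def test_translation_invariance(self):
        fixes = self._daily_fixes()
        shifted = make_fixes(
            [(f.latitude + 0.5, f.longitude - 0.5) for f in fixes],
            step_minutes=30)
        a = circadian_movement(fixes)
        b = circadian_movement(shifted)
        assert b.cm == pytest.approx(a.cm, rel=1e-9)

    def test_short_series_flagged_low_confidence(self):
        fixes = self._daily_fixes()[:48]  # spans 24 h only
        assert circadian_movement(fixes).low_confidence

    def test_frequency_grid_spans_bin(self):
        grid = cm_frequency_grid((23.5, 24.5), 24)
        assert grid.size == 24
        assert 1 / grid.max() == pytest.approx(23.5)
        assert 1 / grid.min() == pytest.approx(24.5)


class TestWeeklyCmReliability:
    def test_identical_weeks_alpha_one(self):
        col = np.array([0.3, -0.2, 1.1, 0.7])
        assert weekly_cm_reliability(np.tile(col[:, None], 4)) == pytest.approx(1.0)

    def test_toy_matrix_alpha_one(self):
        # items perfectly correlated with equal variances: by hand,
        # item variances 1 + 1, total variance 4 -> alpha = 2*(1 - 2/4) = 1
        m = np.array([[1, 2], [2, 3], [3, 4]], dtype=float)
        assert weekly_cm_reliability(m) == pytest.approx(1.0)

    def test_independent_columns_alpha_near_zero(self):
        rng = np.random.default_rng(6)
        m = rng.normal(size=(200, 4))
        assert abs(weekly_cm_reliability(m)) < 0.15

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(7)
        base = rng.normal(size=50)
        m = base[:, None] + rng.normal(0, 0.8, size=(50, 4))
        alpha = weekly_cm_reliability(m)
        ref = pg.cronbach_alpha(pd.DataFrame(m))[0]
        assert alpha == pytest.approx(ref, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            weekly_cm_reliability(np.ones((4, 3)))  # zero variance
        with pytest.raises(ValueError):
            weekly_cm_reliability(np.array([[1.0], [2.0]]))  # one week
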