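"""Tests of the MSD/MSC/angle/radius statistics and the statistical tests."""

import numpy as np
import pytest
from scipy import stats

import pcmotion as pm

from conftest import make_track


class TestMsd:
    def test_constant_track_zero_msd(self):
        curve = pm.compute_msd(make_track(np.ones((20, 2))))
        assert np.all(curve.msd_um2 == 0.0)

    def test_ballistic_closed_form(self):
        s = 0.1
        xy = np.arange(30)[:, None] * [s, 0.0]
        curve = pm.compute_msd(make_track(xy))
        k = np.arange(1, 30)
        assert np.allclose(curve.msd_um2, (k * s) ** 2)

    def test_lag_exceeding_span_is_noted(self):
        track = make_track(np.zeros((5, 2)))
        curve = pm.compute_msd(track, lags_s=[0.25, 10.0])
        assert curve.lag_s.tolist() == [0.25]
        assert any("exceeds" in note for note in curve.notes)

    def test_brownian_matches_4dt_within_5pct(self):
        d = 0.02
        ts = pm.simulate_brownian_tracks(500, 61, 0.25, d, seed=2)
        ens = pm.ensemble_curve([pm.compute_msd(t) for t in ts.tracks])
        rel = ens.msd_um2[:5] / (4 * d * ens.lag_s[:5]) - 1.0
        assert np.all(np.abs(rel) < 0.05)


class TestMsc:
    def test_identical_tracks_zero(self, rng):
        xy = rng.normal(size=(25, 2))
        a, b = make_track(xy, object_id=0), make_track(xy, object_id=1)
        assert np.all(pm.compute_msc(a, b).msc_um2 == 0.0)

    def test_radial_recession_closed_form(self):
        s = 0.2
        static = make_track(np.zeros((20, 2)), object_id=0)
        receding = make_track(np.column_stack(
            [1.0 + np.arange(20) * s, np.zeros(20)]), object_id=1)
        curve = pm.compute_msc(static, receding)
        k = np.arange(1, 20)
        assert np.allclose(curve.msc_um2, (k * s) ** 2)

    def test_frame_mismatch_raises(self):
        a = make_track(np.zeros((10, 2)))
        b = make_track(np.zeros((9, 2)), object_id=1)
        with pytest.raises(ValueError):
            pm.compute_msc(a, b)

    def test_far_separated_brownian_pairs_radial_limit(self):
        # far apart, the distance change projects both motions on the
        # separation axis: MSC(dt) -> 2 (D1 + D2) dt
        d1, d2 = 0.02, 0.03
        n_pairs, n_frames = 300, 81
        ts1 = pm.simulate_brownian_tracks(n_pairs, n_frames, 0.25, d1, seed=3)
        ts2 = pm.simulate_brownian_tracks(n_pairs, n_frames, 0.25, d2, seed=4)
        curves = []
        for a, b in zip(ts1.tracks, ts2.tracks):
            far = b.with_positions(b.xy_um + [1000.0, 0.0])
            far.object_id = a.object_id + 10_000
            curves.append(pm.compute_msc(a, far, lags_s=[0.25, 0.5, 0.75]))
        mean = np.mean([c.msc_um2 for c in curves], axis=0)
        expected = 2 * (d1 + d2) * np.array([0.25, 0.5, 0.75])
        assert np.all(np.abs(mean / expected - 1.0) < 0.1)


class TestOverT:
    def test_ballistic_increases(self):
        curve = pm.MsdCurve(lag_s=np.array([1.0, 2.0, 3.0]),
                            msd_um2=np.array([1.0, 4.0, 9.0]),
                            n_pairs=np.ones(3))
        rate = pm.msd_over_t(curve)
        assert np.all(np.diff(rate.rate_um2_s) > 0)

    def test_plateau_decays_as_one_over_t(self):
        lags = np.array([1.0, 2.0, 4.0])
        curve = pm.MsdCurve(lag_s=lags, msd_um2=np.full(3, 0.04),
                            n_pairs=np.ones(3))
        rate = pm.msd_over_t(curve)
        assert np.allclose(rate.rate_um2_s, 0.04 / lags)

    def test_free_brownian_is_flat_at_4d(self):
        d = 0.015
        ts = pm.simulate_brownian_tracks(400, 41, 0.25, d, seed=5)
        ens = pm.ensemble_curve([pm.compute_msd(t) for t in ts.tracks])
        rate = pm.msd_over_t(ens)
        assert np.all(np.abs(rate.rate_um2_s[:8] / (4 * d) - 1.0) < 0.07)


class TestTurningAngles:
    def test_straight_line_gives_180(self):
        track = make_track(np.arange(10)[:, None] * [0.1, 0.0])
        angles, _ = pm.turning_angles(track, 0.25)
        assert np.allclose(angles, 180.0)

    def test_back_and_forth_gives_0(self):
        xy = np.zeros((12, 2))
        xy[1::2, 0] = 0.3
        angles, _ = pm.turning_angles(make_track(xy), 0.25)
        assert np.allclose(angles, 0.0)

    def test_brownian_angles_uniform(self):
        # chi-square over 6 bins must not reject uniformity at p = 0.01
        ts = pm.simulate_brownian_tracks(200, 61, 0.25, 0.01, seed=6)
        hist = pm.turning_angle_histogram(ts.tracks, 0.25)
        assert hist.n_angles >= 10_000
        counts = hist.frequency * hist.n_angles
        chi2 = ((counts - hist.n_angles / 6) ** 2 / (hist.n_angles / 6)).sum()
        assert stats.chi2.sf(chi2, df=5) > 0.01

    def test_confined_tracks_overrepresent_narrow_angles(self, quiet_preset):
        preset = quiet_preset.replace(localization_noise_sd_um=0.0)
        sim = pm.simulate_tracks(preset, 20, seed=7)
        lag = 3 * preset.relaxation_time_s
        hist = pm.turning_angle_histogram(sim.tracks, lag)
        assert hist.frequency[:2].sum() > 1.0 / 3.0   # P(theta < 60 deg)

    def test_all_zero_displacements_warn(self):
        track = make_track(np.zeros((10, 2)))
        with pytest.warns(UserWarning):
            hist = pm.turning_angle_histogram([track], 0.25)
        assert hist.n_angles == 0


class TestRadii:
    def test_constant_plateau_definition(self):
        lags = np.arange(1, 12) * 1.0
        curve = pm.MsdCurve(lag_s=lags, msd_um2=np.full(11, 0.04),
                            n_pairs=np.ones(11))
        est = pm.confinement_radius(curve, window_s=(3, 10))
        assert est.radius_um == pytest.approx(0.2)

    def test_window_outside_curve_raises(self):
        curve = pm.MsdCurve(lag_s=np.array([0.25, 0.5]),
                            msd_um2=np.zeros(2), n_pairs=np.ones(2))
        with pytest.raises(ValueError):
            pm.confinement_radius(curve, window_s=(3, 10))

    def test_uniform_disc_resampling_recovers_radius(self, rng):
        # independent uniform positions in a disc of radius R give
        # E|r1 - r2|^2 = R^2 at every lag
        big_r = 0.5
        n = 100_000
        radius = big_r * np.sqrt(rng.uniform(size=n))
        theta = rng.uniform(0, 2 * np.pi, size=n)
        xy = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        curve = pm.compute_msd(make_track(xy), lags_s=[1.0, 2.0])
        est = pm.confinement_radius(curve, window_s=(1, 2))
        assert abs(est.radius_um / big_r - 1.0) < 0.03

    def test_ou_tracks_recover_two_sigma(self, quiet_preset):
        preset = quiet_preset.replace(localization_noise_sd_um=0.0,
                                      confinement_radius_cv=0.0,
                                      intensity_mobility_exponent=0.0)
        sim = pm.simulate_tracks(preset, 20, seed=8)
        ens = pm.ensemble_curve([pm.compute_msd(t) for t in sim.tracks])
        est = pm.confinement_radius(ens, window_s=(3, 10))
        sigma = preset.confinement_radius_um / 2
        assert abs(est.radius_um / (2 * sigma) - 1.0) < 0.05

    def test_radius_at_lag(self):
        curve = pm.MsdCurve(lag_s=np.array([1.0]), msd_um2=np.array([0.01]),
                            n_pairs=np.ones(1))
        assert pm.radius_at_lag(curve, 1.0) == pytest.approx(0.1)
        with pytest.raises(ValueError):
            pm.radius_at_lag(curve, 2.0)

    def test_monotone_msd_gives_monotone_radius(self):
        lags = np.arange(1, 6) * 1.0
        curve = pm.MsdCurve(lag_s=lags, msd_um2=lags * 0.01, n_pairs=np.ones(5))
        radii = [pm.radius_at_lag(curve, lag) for lag in lags]
        assert np.all(np.diff(radii) > 0)


class TestTerritoryRadius:
    @pytest.mark.parametrize("area,expected", [(23.0, 0.86), (16.0, 0.71),
                                               (14.0, 0.67)])
    def test_printed_stage_values(self, area, expected):
        assert pm.territory_radius(area, 10) == pytest.approx(expected)

    def test_unit_disc(self):
        assert pm.territory_radius(np.pi, 1) == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pm.territory_radius(-1.0, 10)
        with pytest.raises(ValueError):
            pm.territory_radius(10.0, 0)


class TestCorrelation:
    def test_perfect_correlation(self, rng):
        x = rng.lognormal(size=50)
        res = pm.msd_msc_correlation(x, x)
        assert res.r == pytest.approx(1.0)

    def test_independent_pairs_uncorrelated(self, rng):
        x = rng.lognormal(size=1000)
        y = rng.lognormal(size=1000)
        res = pm.msd_msc_correlation(x, y)
        assert abs(res.r) < 0.1 and res.pvalue > 0.01

    def test_reciprocal_gives_minus_one(self, rng):
        x = rng.lognormal(size=40)
        res = pm.msd_msc_correlation(x, 1.0 / x)
        assert res.r == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pm.msd_msc_correlation(np.ones(10), np.arange(1, 11))


class TestKs:
    def test_identical_samples_d_zero(self, rng):
        x = rng.normal(size=30)
        assert pm.two_sample_ks(x, x, method="asymp").statistic == 0.0

    def test_disjoint_supports_d_one(self):
        res = pm.two_sample_ks(np.arange(10), np.arange(100, 110),
                               method="asymp")
        assert res.statistic == 1.0

    def test_statistic_matches_bruteforce_ecdf_scan(self, rng):
        a = rng.normal(size=50)
        b = rng.normal(0.4, 1.2, size=60)
        res = pm.two_sample_ks(a, b, method="asymp")
        grid = np.concatenate([a, b])
        ecdf_a = np.mean(a[:, None] <= grid[None, :], axis=0)
        ecdf_b = np.mean(b[:, None] <= grid[None, :], axis=0)
        assert res.statistic == pytest.approx(np.max(np.abs(ecdf_a - ecdf_b)))

    def test_permutation_close_to_asymptotic_at_50_50(self, rng):
        a = rng.normal(size=50)
        b = rng.normal(0.35, 1.0, size=50)
        asymp = pm.two_sample_ks(a, b, method="asymp")
        perm = pm.two_sample_ks(a, b, method="permutation",
                                n_permutations=20_000, seed=0)
        assert perm.statistic == asymp.statistic
        assert abs(perm.pvalue - asymp.pvalue) / asymp.pvalue < 0.1

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            pm.two_sample_ks(np.array([]), np.arange(3))


class TestLogTTest:
    def test_equal_samples_give_t_zero(self, rng):
        x = rng.lognormal(size=20)
        res = pm.log_t_test(x, x)
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_common_scale_factor_leaves_t_unchanged(self, rng):
        a = rng.lognormal(size=25)
        b = rng.lognormal(0.5, 1.0, size=30)
        t0 = pm.log_t_test(a, b).statistic
        t1 = pm.log_t_test(7.3 * a, 7.3 * b).statistic
        assert t1 == pytest.approx(t0)

    def test_nonpositive_values_raise(self):
        with pytest.raises(ValueError):
            pm.log_t_test(np.array([1.0, -1.0, 2.0]), np.array([1.0, 2.0]))


class TestInvariances:
    def test_msd_rigid_motion_invariant(self, rng):
        xy = rng.normal(size=(40, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = xy @ rot.T + [5.0, -3.0]
        a = pm.compute_msd(make_track(xy))
        b = pm.compute_msd(make_track(moved))
        assert np.allclose(a.msd_um2, b.msd_um2)

    def test_msc_joint_rigid_motion_invariant(self, rng):
        xy1 = rng.normal(size=(30, 2))
        xy2 = rng.normal(size=(30, 2)) + [2.0, 0.0]
        theta = -1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        c0 = pm.compute_msc(make_track(xy1), make_track(xy2, object_id=1))
        c1 = pm.compute_msc(make_track(xy1 @ rot.T + 4.0),
                            make_track(xy2 @ rot.T + 4.0, object_id=1))
        assert np.allclose(c0.msc_um2, c1.msc_um2)

    def test_msc_equal_on_relative_coords_without_drift(self, quiet_preset):
        sim = pm.simulate_tracks(quiet_preset, 1, seed=9)
        rel = pm.to_relative(sim.trackset, sim.nucleus_traces)
        a, b = sim.tracks[0], sim.tracks[1]
        ra, rb = rel[0], rel[1]
        assert np.allclose(pm.compute_msc(a, b).msc_um2,
                           pm.compute_msc(ra, rb).msc_um2)
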