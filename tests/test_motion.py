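"""MSD computation, model fits, classification, filtering and kinematics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcclutch import (ClassThresholds, SimConfig, Track, TrackSet, class_fractions,
                      classify_alpha, classify_mobility, classify_trackset,
                      compute_msd, diffusion_from_initial_slope, eb3_metrics,
                      filter_tracks, fit_msd_directed, fit_msd_power,
                      growth_cone_kinematics, resolution_d_threshold)
from gcclutch.motion import MSDCurve

from conftest import make_brownian_track, make_linear_track, make_trackset


def brute_force_msd(track, max_lag):
    """Independent double-loop-over-all-pairs MSD."""
    p = track.positions()
    out = []
    for m in range(1, max_lag + 1):
        acc = [np.sum((p[i + m] - p[i]) ** 2) for i in range(len(p) - m)]
        out.append(np.mean(acc))
    return np.array(out)


class TestComputeMSD:
    def test_stationary_track_has_zero_msd(self):
        tr = make_linear_track(v=(0.0, 0.0), n=10)
        assert np.all(compute_msd(tr).values == 0.0)

    def test_uniform_motion_msd_is_v_squared_tau_squared(self):
        v = 0.1
        tr = make_linear_track(v=(v, 0.0), dt=0.5, n=20)
        msd = compute_msd(tr)
        np.testing.assert_allclose(msd.values, v ** 2 * msd.lags ** 2,
                                   rtol=1e-12)

    def test_matches_brute_force_pair_sum(self, rng):
        tr = make_brownian_track(rng, n=10)
        msd = compute_msd(tr)
        np.testing.assert_allclose(msd.values, brute_force_msd(tr, len(msd)),
                                   rtol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n=st.integers(5, 50), seed=st.integers(0, 2 ** 20))
    def test_brute_force_equivalence_any_short_track(self, n, seed):
        tr = make_brownian_track(np.random.default_rng(seed), n=n)
        msd = compute_msd(tr)
        np.testing.assert_allclose(msd.values, brute_force_msd(tr, len(msd)),
                                   rtol=1e-10)

    def test_n_pairs_bookkeeping(self):
        tr = make_linear_track(n=10)
        msd = compute_msd(tr)
        np.testing.assert_array_equal(msd.n_pairs, np.arange(9, 0, -1))

    def test_too_short_track_raises(self):
        tr = make_linear_track(n=1)
        with pytest.raises(ValueError):
            compute_msd(tr)


class TestPowerLawFit:
    def test_pure_drift_gives_alpha_two(self):
        t = np.arange(1, 21) * 0.5
        msd = MSDCurve(t, (0.1 ** 2) * t ** 2, np.full(20, 10))
        fit = fit_msd_power(msd)
        assert fit.alpha == pytest.approx(2.0, abs=1e-6)

    def test_pure_brownian_recovers_alpha_and_d(self):
        t = np.arange(1, 21) * 0.5
        msd = MSDCurve(t, 4 * 0.05 * t, np.full(20, 10))
        fit = fit_msd_power(msd)
        assert fit.alpha == pytest.approx(1.0, abs=1e-9)
        assert fit.D == pytest.approx(0.05, rel=1e-9)

    def test_all_zero_msd_flagged_degenerate(self):
        t = np.arange(1, 11) * 0.5
        fit = fit_msd_power(MSDCurve(t, np.zeros(10), np.full(10, 5)))
        assert fit.degenerate and fit.D == 0.0

    def test_brownian_ensemble_parameter_recovery(self):
        """200 simulated Brownian tracks (D = 0.05, 20 Hz, 20 frames):
        median alpha near 1, median D within 20% of truth."""
        rng = np.random.default_rng(2)
        fits = [fit_msd_power(compute_msd(
            make_brownian_track(rng, D=0.05, dt=0.05, n=20, track_id=i)))
            for i in range(200)]
        alphas = np.median([f.alpha for f in fits])
        Ds = np.median([f.D for f in fits])
        assert 0.8 <= alphas <= 1.2
        assert abs(Ds - 0.05) / 0.05 <= 0.2


class TestDirectedFit:
    def test_exact_recovery_of_d_and_v(self):
        t = np.arange(1, 21) * 0.5
        msd = MSDCurve(t, 4 * 0.01 * t + 0.01 * t ** 2, np.full(20, 10))
        fit = fit_msd_directed(msd)
        assert fit.D == pytest.approx(0.01, abs=1e-6)
        assert fit.V == pytest.approx(0.1, abs=1e-6)

    def test_zero_msd_gives_zero_parameters(self):
        t = np.arange(1, 11) * 0.5
        fit = fit_msd_directed(MSDCurve(t, np.zeros(10), np.full(10, 5)))
        assert fit.D == 0.0 and fit.V == 0.0

    def test_negative_curvature_clamped_and_flagged(self):
        # concave MSD: quadratic term would be negative without the bound
        t = np.arange(1, 21) * 0.5
        msd = MSDCurve(t, 4 * 0.05 * np.sqrt(t), np.full(20, 10))
        fit = fit_msd_directed(msd)
        assert fit.V == 0.0 and fit.degenerate


class TestClassification:
    @pytest.mark.parametrize("alpha,expected", [
        (1.6, "directed"),
        (1.5, "directed"),      # boundary inclusive
        (1.49, "brownian"),
        (0.5, "brownian"),      # lower boundary exclusive
        (0.49, "confined"),
        (0.0, "confined"),
    ])
    def test_alpha_thresholds(self, alpha, expected):
        assert classify_alpha(alpha) == expected

    @pytest.mark.parametrize("D,expected", [
        (0.01, "confined"),
        (1e-5, "confined"),     # sentinel
        (0.015, "mobile"),      # strict <
        (0.05, "mobile"),
    ])
    def test_mobility_thresholds(self, D, expected):
        assert classify_mobility(D) == expected

    def test_vangl2_threshold_is_configurable(self):
        th = ClassThresholds(D_confined=0.022)
        assert classify_mobility(0.018, th) == "confined"
        assert classify_mobility(0.018) == "mobile"

    def test_class_fractions_sum_to_one(self, rng):
        tracks = [make_brownian_track(rng, n=20, track_id=i)
                  for i in range(30)]
        table = classify_trackset(make_trackset(tracks, 0.05))
        fr = class_fractions(table)
        assert fr.sum() == pytest.approx(1.0)


class TestInitialSlope:
    def test_linear_msd_recovers_d(self):
        t = np.arange(1, 11) * 0.02
        msd = MSDCurve(t, 4 * 0.1 * t, np.full(10, 5))
        assert diffusion_from_initial_slope(msd) == pytest.approx(0.1)

    def test_negative_slope_returns_sentinel(self):
        t = np.arange(1, 11) * 0.02
        msd = MSDCurve(t, 1.0 - 0.5 * t, np.full(10, 5))
        assert diffusion_from_initial_slope(msd) == 1e-5

    def test_matches_closed_form_ols_slope(self, rng):
        t = np.arange(1, 11) * 0.05
        v = 4 * 0.08 * t + rng.normal(0, 0.01, 10)
        msd = MSDCurve(t, v, np.full(10, 5))
        n = 4
        tm, vm = t[:n].mean(), v[:n].mean()
        slope = np.sum((t[:n] - tm) * (v[:n] - vm)) / np.sum((t[:n] - tm) ** 2)
        assert diffusion_from_initial_slope(msd, n) == pytest.approx(slope / 4)

    def test_resolution_threshold_helper_formula(self):
        # res^2 / (4 * n * dt); the canonical inputs evaluate to ~0.038
        assert resolution_d_threshold(0.11, 4, 0.02) == pytest.approx(
            0.11 ** 2 / (4 * 4 * 0.02))


class TestFilterTracks:
    def test_eight_frames_kept_seven_dropped(self):
        ts = make_trackset([make_linear_track(n=8, track_id=0),
                            make_linear_track(n=7, track_id=1)], 0.5)
        kept = filter_tracks(ts, min_frames=7)
        assert [tr.id for tr in kept] == [0]

    def test_empty_set_stays_empty(self):
        assert len(filter_tracks(TrackSet([], 0.5))) == 0

    def test_survivor_count_matches_exhaustive_count(self):
        lengths = [2, 5, 7, 8, 8, 9, 12, 20, 3, 7]
        ts = make_trackset([make_linear_track(n=n, track_id=i)
                            for i, n in enumerate(lengths)], 0.5)
        kept = filter_tracks(ts)
        assert len(kept) == sum(1 for n in lengths if n > 7)

    def test_idempotent(self):
        lengths = [5, 8, 12]
        ts = make_trackset([make_linear_track(n=n, track_id=i)
                            for i, n in enumerate(lengths)], 0.5)
        once = filter_tracks(ts)
        twice = filter_tracks(once)
        assert [tr.id for tr in twice] == [tr.id for tr in once]


class TestKinematics:
    def test_total_path_over_total_time(self):
        # 45 µm over 45 min at 1 frame/min -> 1 µm/min
        t = np.arange(46) * 60.0
        tr = Track(0, t, np.linspace(0, 45, 46), np.zeros(46), 60.0)
        res = growth_cone_kinematics(tr)
        assert res.mean_velocity == pytest.approx(1.0)

    def test_ninety_second_hold_is_one_pause(self):
        t = np.arange(0, 300, 30.0)
        x = np.where(t <= 90, 0.0, (t - 90) * 0.01)
        tr = Track(0, t, x, np.zeros_like(t), 30.0)
        res = growth_cone_kinematics(tr, pause_min=60.0, pause_eps=0.5)
        assert res.n_pauses == 1
        start, duration = res.pauses[0]
        assert duration >= 90.0

    def test_constructed_pauses_recovered(self):
        """Three built-in pauses with known durations are all detected."""
        dt = 60.0
        segments = []
        x = [0.0]
        pause_frames = [3, 2, 4]  # 180 s, 120 s, 240 s holds
        for i, pf in enumerate(pause_frames):
            x.extend([x[-1]] * pf)          # hold
            x.extend([x[-1] + 2.0 * (k + 1) for k in range(3)])  # move
        x = np.array(x)
        t = np.arange(len(x)) * dt
        tr = Track(0, t, x, np.zeros_like(x), dt)
        res = growth_cone_kinematics(tr, pause_min=60.0, pause_eps=0.5)
        assert res.n_pauses == 3
        assert [d for _, d in res.pauses] == [180.0, 120.0, 240.0]
        assert res.total_pause_time == pytest.approx(540.0)
        assert res.velocity_excluding_pauses > res.mean_velocity

    def test_single_sample_raises(self):
        tr = make_linear_track(n=1)
        with pytest.raises(ValueError):
            growth_cone_kinematics(tr)


class TestEB3:
    def test_lifetime_is_points_over_rate(self):
        assert eb3_metrics(make_linear_track(n=20, dt=0.5)).lifetime == 10.0
        assert eb3_metrics(make_linear_track(n=2, dt=0.5)).lifetime == 1.0

    def test_comet_velocity_recovered_within_ten_percent(self, rng):
        v = 0.2
        fits = []
        for i in range(30):
            t = np.arange(20) * 0.5
            x = v * t + rng.normal(0, 0.02, 20)
            y = rng.normal(0, 0.02, 20)
            fits.append(eb3_metrics(Track(i, t, x, y, 0.5)).V)
        assert abs(np.mean(fits) - v) / v <= 0.1


class TestRegimePureClasses:
    """Tracks simulated in a single kinetic regime classify as expected:
    free monomers are Brownian, flowing filaments directed, and
    adhesion-bound molecules confined (by the mobility/D classifier —
    their residual motion is slow but unconstrained, so alpha stays near 1)."""

    def _downsampled(self, cfg, state, n_tracks, seed0, **kw):
        from gcclutch import CameraConfig, downsample_to_camera
        from gcclutch.clutch import ClutchSimulator
        sim = ClutchSimulator(cfg)
        out = []
        for i in range(n_tracks):
            tr = sim.simulate_molecule(np.random.default_rng(seed0 + i), i,
                                       initial_state=state, **kw)
            ds = downsample_to_camera(
                TrackSet([tr.slice(0, 400)], cfg.dt), CameraConfig())
            out.append(ds[0])
        return out

    def test_free_only_predominantly_brownian(self):
        from gcclutch.tracks import FREE
        cfg = SimConfig(k_poly=0.0, seed=0)
        tracks = self._downsampled(cfg, FREE, 40, 4000)
        cls = [classify_alpha(fit_msd_power(compute_msd(tr)))
               for tr in tracks]
        assert cls.count("brownian") / len(cls) > 0.6

    def test_bound_only_predominantly_confined_by_mobility(self):
        from gcclutch.tracks import BOUND
        cfg = SimConfig(k_u=0.0, seed=0)
        tracks = self._downsampled(cfg, BOUND, 40, 5000, r0=8.0)
        mob = [classify_mobility(
            diffusion_from_initial_slope(compute_msd(tr))) for tr in tracks]
        assert mob.count("confined") / len(mob) > 0.9

    def test_flow_only_predominantly_directed(self):
        from gcclutch.tracks import FLOW
        cfg = SimConfig(k_c=0.0, k_d=0.0, V_flow=0.1, seed=0)
        tracks = self._downsampled(cfg, FLOW, 40, 6000, r0=11.0, theta0=0.0)
        cls = [classify_alpha(fit_msd_power(compute_msd(tr)))
               for tr in tracks]
        assert cls.count("directed") / len(cls) > 0.6
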