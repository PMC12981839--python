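"""Gait generator, frame renderer, optics forward model, delay model and
state-trial generators."""
import numpy as np
import pytest

from stimloop import behavior_analysis as ba
from stimloop import calibration as cal
from stimloop import multichamber as mc
from stimloop import virtual_rig as rig
from stimloop.virtual_rig import (
    GaitParams,
    LatencyModel,
    MovementStateParams,
    OpticsModel,
    StateTrajectoryParams,
    _truncnorm_loc_for_mean,
)


class TestSimulateGait:
    def test_seed_is_required(self):
        with pytest.raises(ValueError, match="seed"):
            rig.simulate_gait(GaitParams(), 5.0)

    def test_zero_body_speed_means_fully_static_paws(self):
        pose = rig.simulate_gait(GaitParams(body_speed_px_s=0.0), 10.0, seed=1)
        for part in ("left_hindpaw_mid", "right_hindpaw_mid"):
            x, y, _ = pose.part(part)
            assert np.ptp(x) == 0.0 and np.ptp(y) == 0.0
            res = ba.gait_phases(ba.preprocess(pose, part, jump_px=np.inf))
            assert np.mean(res.static_labels) == 1.0

    def test_equal_stance_swing_gives_half_duty_cycle(self):
        params = GaitParams(stance_mean_ms=200.0, stance_sd_ms=0.0,
                            swing_mean_ms=200.0, swing_sd_ms=0.0)
        pose = rig.simulate_gait(params, 60.0, seed=2)
        traj = ba.preprocess(pose, "left_hindpaw_mid", jump_px=np.inf)
        res = ba.gait_phases(traj)
        one_frame = 1000.0 / 30.0
        assert abs(res.stance_mean_ms - 200.0) <= one_frame
        assert abs(res.swing_mean_ms - 200.0) <= one_frame
        duty = np.mean(res.static_labels)
        assert abs(duty - 0.5) <= 0.02

    def test_left_right_hind_paws_out_of_phase(self):
        pose = rig.simulate_gait(GaitParams(), 60.0, seed=3)
        left = ba.gait_phases(ba.preprocess(pose, "left_hindpaw_mid", jump_px=np.inf))
        right = ba.gait_phases(ba.preprocess(pose, "right_hindpaw_mid", jump_px=np.inf))
        both_swing = (~left.static_labels) & (~right.static_labels)
        # with a 0.5 phase offset and ~22% swing duty, simultaneous swing of
        # both hind paws should be rare
        assert np.mean(both_swing) < 0.05

    def test_tail_base_advances_at_body_speed(self):
        pose = rig.simulate_gait(GaitParams(body_speed_px_s=170.0), 20.0, seed=4)
        x, _, _ = pose.part("tail_base")
        per_frame = np.abs(np.diff(x))
        np.testing.assert_allclose(np.median(per_frame), 170.0 / 30.0, rtol=1e-6)

    def test_likelihood_dropout_fraction(self):
        params = GaitParams(dropout_fraction=0.1)
        pose = rig.simulate_gait(params, 60.0, seed=5)
        frac = np.mean(pose.likelihood == params.dropout_likelihood)
        assert 0.07 < frac < 0.13
        assert np.all((pose.likelihood == 0.95) | (pose.likelihood == 0.3))

    def test_identical_seed_identical_output(self):
        a = rig.simulate_gait(GaitParams(), 10.0, seed=6)
        b = rig.simulate_gait(GaitParams(), 10.0, seed=6)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.likelihood, b.likelihood)

    def test_static_fraction_decreases_across_speed_presets(self):
        fracs = []
        for i, (name, params) in enumerate(rig.SPEED_PRESETS.items()):
            pose = rig.simulate_gait(params, 60.0, seed=100 + i)
            res = ba.gait_phases(ba.preprocess(pose, "left_hindpaw_mid", jump_px=np.inf))
            fracs.append(np.mean(res.static_labels))
        assert all(a > b for a, b in zip(fracs, fracs[1:]))


class TestRenderFrames:
    def test_static_pose_zero_motion_energy_without_noise(self):
        from stimloop.core_io import PoseSeries

        pose = PoseSeries(("a",), np.full((4, 1), 30.0), np.full((4, 1), 30.0),
                          np.ones((4, 1)), frame_size=(64, 64))
        fs = rig.render_frames(pose, blob_sd_px=2.0)
        assert mc.motion_energy(fs, noise_floor=10).max() == 0.0

    def test_moving_blob_energy_concentrates_near_path(self):
        from stimloop.core_io import PoseSeries

        pose = PoseSeries(("a",), np.array([[20.0], [40.0]]),
                          np.array([[32.0], [32.0]]), np.ones((2, 1)),
                          frame_size=(96, 96))
        fs = rig.render_frames(pose, blob_sd_px=2.0)
        diff = np.abs(fs.frames[1].astype(int) - fs.frames[0].astype(int)).astype(float)
        diff[diff < 10] = 0
        ys, xs = np.nonzero(diff)
        assert diff.sum() > 0
        assert np.all(np.abs(ys - 32) <= 3 * 2.0)
        assert xs.min() >= 20 - 6 and xs.max() <= 40 + 6

    def test_noise_only_scene_stays_below_idle_threshold(self):
        from stimloop.core_io import PoseSeries

        n = 70
        pose = PoseSeries(("a",), np.full((n, 1), 32.0), np.full((n, 1), 32.0),
                          np.ones((n, 1)), frame_size=(64, 64))
        fs = rig.render_frames(pose, blob_sd_px=2.0, background_noise_sd=1.0, seed=1)
        trace = mc.motion_energy(fs, noise_floor=10)
        assert np.all(trace < 30000)
        assert mc.detect_idle(trace, fps=30.0)[-1]

    def test_out_of_frame_pose_rejected(self):
        from stimloop.core_io import PoseSeries

        pose = PoseSeries(("a",), np.array([[100.0]]), np.array([[10.0]]),
                          np.zeros((1, 1)), frame_size=(64, 64))
        with pytest.raises(ValueError, match="frame"):
            rig.render_frames(pose, blob_sd_px=2.0)


class TestOpticsForward:
    def test_identity_optics_is_exact_inverse_gain(self, identity_optics):
        v = np.array([2.0, 7.0])
        px = rig.optics_forward(v, identity_optics, noise=False)
        np.testing.assert_allclose(px, v / 0.01)

    def test_quadratic_distortion_matches_hand_computed_polynomial(self):
        # monomial order: 1, v, u, v^2, u*v, u^2 (u, v normalized to [-1, 1])
        cx = (1.0, 0.0, 2.0, 0.0, 0.0, 3.0)
        cy = (0.0, -1.0, 0.0, 0.5, 2.0, 0.0)
        model = OpticsModel(distortion_coeff_x=cx, distortion_coeff_y=cy,
                            noise_sd_px=0.0)
        volts = np.array([3.3, 7.7])
        lin = volts / 0.01
        u = 2 * lin[0] / 1100 - 1
        v = 2 * lin[1] / 1100 - 1
        dx = 1.0 + 2.0 * u + 3.0 * u**2
        dy = -1.0 * v + 2.0 * u * v + 0.5 * v**2
        px = rig.optics_forward(volts, model, noise=False)
        np.testing.assert_allclose(px, [lin[0] + dx, lin[1] + dy], rtol=1e-12)

    def test_distinct_voltages_give_distinct_pixels(self, calibrated_rig):
        optics, _ = calibrated_rig
        a = rig.optics_forward(np.array([3.0, 3.0]), optics, noise=False)
        b = rig.optics_forward(np.array([3.01, 3.0]), optics, noise=False)
        assert not np.allclose(a, b)

    def test_out_of_range_voltage_refused(self, identity_optics):
        with pytest.raises(ValueError, match="range"):
            rig.optics_forward(np.array([99.0, 0.0]), identity_optics, noise=False)

    def test_noiseless_forward_bijective_via_fitted_inverse(self, calibrated_rig):
        optics, cmap = calibrated_rig
        rng = np.random.default_rng(0)
        (x0, x1), (y0, y1) = cmap.domain
        pts = np.column_stack([rng.uniform(x0 + 30, x1 - 30, 40),
                               rng.uniform(y0 + 30, y1 - 30, 40)])
        volts = cal.predict_voltage(cmap, pts)
        back = rig.optics_forward(volts, optics, noise=False)
        assert np.linalg.norm(back - pts, axis=1).max() < 1.0

    def test_excessive_distortion_rejected(self):
        with pytest.raises(ValueError, match="5%"):
            OpticsModel(distortion_coeff_x=(60.0, 0, 0, 0, 0, 0), noise_sd_px=0.0)

    def test_seeded_noise_reproducible(self, calibrated_rig):
        optics, _ = calibrated_rig
        a = rig.optics_forward(np.array([3.0, 4.0]), optics, seed=5)
        b = rig.optics_forward(np.array([3.0, 4.0]), optics, seed=5)
        np.testing.assert_array_equal(a, b)


class TestLatencyModel:
    def test_sampled_delays_nonnegative_and_near_means(self):
        rng = np.random.default_rng(0)
        d = LatencyModel().sample_delay_s(rng, 4000)
        assert np.all(d >= 0)
        assert abs(d.mean() - 0.0873) < 0.001

    def test_truncation_at_zero(self):
        rng = np.random.default_rng(1)
        model = LatencyModel(processing_mean_ms=1.0, processing_sd_ms=5.0,
                             actuation_mean_ms=0.1, actuation_sd_ms=0.5)
        d = model.sample_delay_s(rng, 2000)
        assert np.all(d >= 0)


class TestStateTrials:
    def test_straight_line_recovers_speed_and_unit_coherence(self):
        params = StateTrajectoryParams(states=(
            MovementStateParams(50.0, 1e-9, 1.0, 0.0, 0.5),
            MovementStateParams(50.0, 1e-9, 1.0, 0.0, 0.5)))
        trials, _ = rig.generate_state_trials(params, 4, seed=0)
        tr = trials[0].slice(0, 60)
        traj = ba.preprocess(tr, "tail_base", jump_px=np.inf)
        _, v_mm = ba.speed(traj)
        assert np.nanmean(v_mm) == pytest.approx(50.0, rel=1e-6)
        assert ba.heading_coherence(traj.x, traj.y) == pytest.approx(1.0, abs=1e-9)

    def test_incoherent_state_yields_low_coherence(self):
        params = StateTrajectoryParams(states=(
            MovementStateParams(50.0, 1.0, 0.1, 0.0, 0.5),
            MovementStateParams(50.0, 1.0, 0.1, 0.0, 0.5)))
        trials, _ = rig.generate_state_trials(params, 100, seed=1)
        rs = []
        for tr in trials:
            pre = tr.slice(0, 60)
            rs.append(ba.heading_coherence(pre.x[:, 0], pre.y[:, 0]))
        rs = np.asarray(rs)
        assert np.mean(rs <= 0.35) >= 0.95
        assert abs(rs.mean() - 0.1) < 0.1

    def test_exact_mixture_allocation_and_labels(self):
        trials, labels = rig.generate_state_trials(rig.PUBLISHED_STATE_PARAMS, 116, seed=2)
        assert len(trials) == 116
        assert int((labels == 0).sum()) == 79  # round(0.681 * 116)

    def test_zero_speed_state_rejected(self):
        with pytest.raises(ValueError, match="speed"):
            MovementStateParams(0.0, 1.0, 0.9, 0.1, 1.0)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            StateTrajectoryParams(states=(
                MovementStateParams(50.0, 1.0, 0.5, 0.1, 0.6),
                MovementStateParams(30.0, 1.0, 0.5, 0.1, 0.6)))

    def test_minimum_two_trials(self):
        with pytest.raises(ValueError):
            rig.generate_state_trials(rig.PUBLISHED_STATE_PARAMS, 1, seed=0)

    def test_seeded_determinism(self):
        a, la = rig.generate_state_trials(rig.PUBLISHED_STATE_PARAMS, 10, seed=3)
        b, lb = rig.generate_state_trials(rig.PUBLISHED_STATE_PARAMS, 10, seed=3)
        np.testing.assert_array_equal(la, lb)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x, tb.x)


class TestLatencyTrialGenerators:
    def test_truncnorm_location_solver_hits_target_mean(self):
        from scipy import stats

        loc = _truncnorm_loc_for_mean(0.81, 1.65, 0.05, 9.9)
        a, b = (0.05 - loc) / 1.65, (9.9 - loc) / 1.65
        assert stats.truncnorm.mean(a, b, loc=loc, scale=1.65) == pytest.approx(0.81, abs=1e-8)

    def test_me_trials_have_artifact_and_sustained_rise(self):
        traces, nominal, lats = rig.generate_me_response_trials(5, seed=0)
        for i in range(5):
            onset = nominal + int(np.argmax(traces[i, nominal - 3 : nominal + 4])) - 3
            assert traces[i, onset] > 10000  # flash artifact
            rise = onset + int(round(lats[i] * 30))
            assert np.all(traces[i, rise:] >= 1000)
            assert np.all(traces[i, :nominal - 3] < 1000)

    def test_pose_trials_baseline_below_threshold(self):
        trials, lats = rig.generate_pose_response_trials(5, seed=0)
        for tr, lat in zip(trials, lats):
            t = tr["timestamps"] - tr["stim_time"]
            pre = t < 0
            bx, by = tr["x"][pre].mean(), tr["y"][pre].mean()
            d = np.hypot(tr["x"] - bx, tr["y"] - by)
            assert np.all(d[pre] < 3.0)
            assert d[t >= lat + 0.1].min() > 3.0
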