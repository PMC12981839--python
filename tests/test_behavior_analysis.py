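"""Preprocessing, speed, gait segmentation, latency pipelines, coherence,
clustering and state-dependence statistics."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stimloop import behavior_analysis as ba
from stimloop import virtual_rig as rig
from stimloop.behavior_analysis import (
    CleanTrajectory,
    FAST,
    SLOW,
    TrialState,
)
from stimloop.core_io import PoseSeries


def _series(x, y=None, lik=None, fps=30.0):
    x = np.asarray(x, dtype=float)
    y = np.full_like(x, 10.0) if y is None else np.asarray(y, dtype=float)
    lik = np.full_like(x, 0.95) if lik is None else np.asarray(lik, dtype=float)
    return PoseSeries(("kp",), x[:, None], y[:, None], lik[:, None], fps=fps,
                      frame_size=(10000, 10000))


def _traj(x, y=None, fps=30.0, scale=0.45):
    x = np.asarray(x, dtype=float)
    y = np.full_like(x, 10.0) if y is None else np.asarray(y, dtype=float)
    n = len(x)
    return CleanTrajectory(x, y, np.full(n, 0.95), np.zeros(n, bool),
                           np.zeros(n, bool), fps, scale)


class TestPreprocess:
    def test_clean_series_is_identity_with_empty_mask(self):
        s = _series(np.full(20, 5.0))
        t = ba.preprocess(s, "kp")
        np.testing.assert_array_equal(t.x, s.x[:, 0])
        assert not t.interpolated.any() and not t.missing.any()

    def test_single_spike_removed_and_midpoint_filled(self):
        x = np.full(11, 100.0)
        x[5] = 150.0  # 50-px glitch
        t = ba.preprocess(_series(x), "kp")
        assert t.interpolated[5] and not t.missing[5]
        assert t.x[5] == pytest.approx(100.0)

    def test_likelihood_threshold_strictness(self):
        x = np.full(9, 10.0)
        lik = np.full(9, 0.82)
        t_arena = ba.preprocess(_series(x, lik=lik), "kp", likelihood_min=0.8)
        assert not t_arena.interpolated.any() and not t_arena.missing.any()
        t_maze = ba.preprocess(_series(x, lik=lik), "kp", likelihood_min=0.85)
        assert t_maze.missing.all()

    def test_boundary_gap_left_missing_not_extrapolated(self):
        lik = np.full(10, 0.95)
        lik[:3] = 0.2
        t = ba.preprocess(_series(np.arange(10.0), lik=lik), "kp")
        assert t.missing[:3].all()
        assert np.isnan(t.x[:3]).all()
        assert np.isfinite(t.x[3:]).all()

    def test_gap_interpolation_uses_three_frame_anchor_means(self):
        # values 0,2,4 | gap | 10,12,14: anchors mean 2 and 12
        x = np.array([0.0, 2.0, 4.0, 99.0, 10.0, 12.0, 14.0])
        lik = np.full(7, 0.95)
        lik[3] = 0.1
        t = ba.preprocess(_series(x, lik=lik), "kp")
        assert t.x[3] == pytest.approx((2.0 + 12.0) / 2)


class TestSpeed:
    def test_static_trajectory_zero_speed(self):
        v_px, v_mm = ba.speed(_traj(np.full(30, 4.0)))
        assert np.nanmax(v_px) == 0.0

    def test_constant_one_px_per_frame(self):
        v_px, v_mm = ba.speed(_traj(np.arange(60.0)))
        np.testing.assert_allclose(v_px, 30.0)
        np.testing.assert_allclose(v_mm, 13.5)

    def test_glitch_removed_upstream_leaves_smooth_trace(self):
        x = np.arange(60.0)
        x[30] += 100.0
        s = _series(x)
        t = ba.preprocess(s, "kp", jump_px=30.0)
        v_px, _ = ba.speed(t)
        assert np.nanmax(v_px) < 60.0

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.normal(2.0, 0.5, 80))
        y = np.cumsum(rng.normal(1.0, 0.5, 80))
        v1, _ = ba.speed(_traj(x, y))
        a = 0.7
        xr = np.cos(a) * x - np.sin(a) * y + 55.0
        yr = np.sin(a) * x + np.cos(a) * y - 13.0
        v2, _ = ba.speed(_traj(xr, yr))
        np.testing.assert_allclose(v1, v2, rtol=1e-9)

    def test_zero_dt_rejected(self):
        t = _traj(np.arange(5.0))
        t.timestamps = np.array([0.0, 1.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            ba.speed(t)


class TestCategorizeSpeed:
    @pytest.mark.parametrize("v,cat", [
        (0.0, "stationary"), (19.9, "stationary"), (20.0, "low"),
        (119.9, "low"), (120.0, "medium"), (219.9, "medium"),
        (220.0, "high"), (500.0, "high"),
    ])
    def test_bin_edges_lower_inclusive(self, v, cat):
        assert ba.categorize_speed(np.array([v]))[0] == cat

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            ba.categorize_speed(np.array([-1.0]))


class TestGaitPhases:
    def test_always_static_is_one_stance_spanning_everything(self):
        res = ba.gait_phases(_traj(np.full(90, 7.0)))
        assert res.static_labels.all()
        # the single run touches both boundaries, so durations are empty but
        # the labels still show a full-length stance
        assert res.stance_durations_ms.size == 0

    def test_square_wave_exact_durations(self):
        # sentinel runs at the edges; interior: 6-frame holds, 3-frame moves
        pos = [0.0] * 4
        level = 0.0
        for _ in range(8):
            level += 30.0
            pos.extend([pos[-1] + 10.0, pos[-1] + 20.0, level][:3])
            pos.extend([level] * 6)
        pos.extend([pos[-1] + 50.0])  # boundary-moving sentinel
        res = ba.gait_phases(_traj(np.array(pos)))
        assert set(np.round(res.swing_durations_ms, 6)) == {100.0}
        assert set(np.round(res.stance_durations_ms, 6)) == {200.0}

    def test_simulator_defaults_recovered_within_two_sem(self):
        from stimloop.workflows import gait_recovery

        res = gait_recovery(seed=123, n_sessions=3, duration_s=60.0)
        assert abs(res.stance_mean_ms - 350.0) < 2 * res.stance_sem_ms + 1.0
        assert abs(res.swing_mean_ms - 100.0) < 2 * res.swing_sem_ms + 1000.0 / 30.0

    def test_short_trajectory_flagged_insufficient(self):
        res = ba.gait_phases(_traj(np.array([0.0, 1.0])))
        assert res.insufficient_data


class TestMotionEnergyLatency:
    def _trace(self, length=600, onset=294):
        tr = np.zeros(length)
        tr[onset] = 40000.0  # flash artifact
        return tr, onset

    def test_flat_trace_is_no_response(self):
        tr, onset = self._trace()
        res = ba.me_latency(tr, onset)
        assert not res.responded and res.latency_s is None

    def test_clean_step_recovers_latency(self):
        tr, onset = self._trace()
        t_lat = 4.74
        tr[onset + int(round(t_lat * 30)):] += 2000.0
        res = ba.me_latency(tr, onset)
        assert res.responded
        assert res.latency_s == pytest.approx(4.74, abs=2 / 30)

    def test_early_burst_excluded_not_idle(self):
        tr, onset = self._trace()
        burst = onset + int(round(0.8 * 30))
        tr[burst : burst + 5] += 1500.0
        res = ba.me_latency(tr, onset)
        assert not res.responded and res.exclusion == "not_idle"

    def test_onset_refinement_tracks_jittered_artifact(self):
        tr = np.zeros(600)
        nominal = 294
        tr[nominal + 3] = 40000.0  # artifact 0.1 s late
        tr[nominal + 3 + 60 :] += 2000.0
        res = ba.me_latency(tr, nominal)
        assert res.responded
        assert res.latency_s == pytest.approx(2.0, abs=2 / 30)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="short"):
            ba.me_latency(np.zeros(100), 50)

    def test_roi_trace_suppression_boundary(self):
        frames = np.zeros((2, 40, 40), dtype=np.uint8)
        frames[1, 20, 20] = 2
        trace, _ = ba.me_roi_trace(frames, (20, 20), radius_px=15, suppress=3)
        assert trace[0] == 0.0
        frames[1, 20, 20] = 3
        trace, _ = ba.me_roi_trace(frames, (20, 20), radius_px=15, suppress=3)
        assert trace[0] == 3.0

    def test_roi_trace_matches_brute_force(self):
        rng = np.random.default_rng(0)
        frames = rng.integers(0, 255, (5, 48, 48)).astype(np.uint8)
        cx, cy, r = 24.0, 20.0, 15.0
        trace, clipped = ba.me_roi_trace(frames, (cx, cy), radius_px=r, suppress=3)
        yy, xx = np.mgrid[0:48, 0:48]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        for k in range(4):
            d = np.abs(frames[k + 1].astype(int) - frames[k].astype(int)).astype(float)
            d[~mask] = 0
            d[d < 3] = 0
            assert trace[k] == pytest.approx(d.sum())

    def test_roi_clipping_flagged(self):
        frames = np.zeros((2, 20, 20), dtype=np.uint8)
        _, clipped = ba.me_roi_trace(frames, (2, 2), radius_px=15)
        assert clipped


class TestPoseLatency:
    def _trial(self, n=361, fps=30.0):
        t = np.arange(n) / fps  # stim at t = 2.0
        x = np.full(n, 100.0)
        y = np.full(n, 100.0)
        lik = np.full(n, 0.95)
        return x, y, lik, t

    def test_static_trajectory_no_response(self):
        x, y, lik, t = self._trial()
        res = ba.pose_latency(x, y, lik, t, stim_time_s=2.0)
        assert not res.responded

    def test_step_latency_recovered(self):
        x, y, lik, t = self._trial()
        onset = 2.0 + 0.81
        x[t >= onset] += 5.0
        res = ba.pose_latency(x, y, lik, t, stim_time_s=2.0)
        assert res.responded
        assert res.latency_s == pytest.approx(0.81, abs=1.01 / 30)

    def test_exactly_three_px_is_not_a_response(self):
        x, y, lik, t = self._trial()
        x[t >= 2.5] += 3.0  # strict > threshold required
        res = ba.pose_latency(x, y, lik, t, stim_time_s=2.0)
        assert not res.responded

    def test_low_likelihood_baseline_excluded(self):
        x, y, lik, t = self._trial()
        lik[t < 2.0] = 0.5
        res = ba.pose_latency(x, y, lik, t, stim_time_s=2.0)
        assert res.exclusion == "low_likelihood"

    def test_latency_pipelines_exact_over_onset_grid(self):
        # constructed single-onset trials: extracted latency within one frame
        fps = 30.0
        for onset in np.arange(0.1, 9.71, 0.4):
            x, y, lik, t = self._trial()
            x[t >= 2.0 + onset] += 5.0
            res = ba.pose_latency(x, y, lik, t, stim_time_s=2.0)
            assert res.responded
            assert abs(res.latency_s - onset) <= 1.0 / fps + 1e-9
        for onset in np.arange(1.6, 9.71, 0.4):
            tr = np.zeros(600)
            tr[294] = 40000.0
            tr[294 + int(round(onset * fps)):] += 2000.0
            res = ba.me_latency(tr, 294)
            assert res.responded
            assert abs(res.latency_s - onset) <= 1.0 / fps + 1e-9

    def test_me_and_pose_latency_agree_on_rendered_fixture(self):
        # one blob that steps 8 px at a known onset, rendered to frames:
        # both pipelines should recover the same latency within 2 frames
        fps = 30.0
        n = 600
        onset_s = 3.0  # relative to stim at t = 9.8 s
        stim_idx = 294
        x = np.full(n, 24.0)
        move_start = stim_idx + int(round(onset_s * fps))
        # withdrawal spread over 6 frames (2 px/frame), as real paws move
        for k in range(6):
            x[move_start + k :] += 2.0
        pose = PoseSeries(("toe",), x[:, None], np.full((n, 1), 32.0),
                          np.full((n, 1), 0.95), fps=fps, frame_size=(64, 64))
        fs = rig.render_frames(pose, blob_sd_px=2.0, blob_amplitude=250.0)
        trace, _ = ba.me_roi_trace(fs, (24.0, 32.0), radius_px=15)
        # express the small-raster blob energy on the analysis scale: the
        # withdrawal burst peaks at ~1.5x the 1000-unit response threshold
        trace = trace * (1500.0 / trace.max())
        trace[stim_idx] += 40000.0
        me = ba.me_latency(trace, stim_idx)
        po = ba.pose_latency(x, np.full(n, 32.0), np.full(n, 0.95),
                             np.arange(n) / fps, stim_time_s=stim_idx / fps)
        assert me.responded and po.responded
        assert abs(me.latency_s - po.latency_s) <= 2.0 / fps + 1e-9


class TestHeadingCoherence:
    def test_straight_line_unit_coherence(self):
        assert ba.heading_coherence(np.arange(80.0), np.zeros(80)) == pytest.approx(1.0)

    def test_exact_reversals_cancel_without_smoothing(self):
        x = np.array([0.0, 1.0] * 30 + [0.0])  # 60 headings: 0/180 alternating
        r = ba.heading_coherence(x, np.zeros_like(x), smooth_window=1)
        assert r == pytest.approx(0.0, abs=1e-12)
        # odd heading count leaves one uncancelled vector
        x_odd = np.array([0.0, 1.0] * 30)
        r_odd = ba.heading_coherence(x_odd, np.zeros_like(x_odd), smooth_window=1)
        assert r_odd == pytest.approx(1.0 / 59.0, abs=1e-12)

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(1)
        th = np.cumsum(rng.normal(0, 0.3, 100))
        x = np.cumsum(np.cos(th))
        y = np.cumsum(np.sin(th))
        r1 = ba.heading_coherence(x, y)
        a = 1.1
        xr = np.cos(a) * x - np.sin(a) * y + 200.0
        yr = np.sin(a) * x + np.cos(a) * y - 40.0
        r2 = ba.heading_coherence(xr, yr)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_displacement_carries_last_heading(self):
        x = np.array([0.0, 1.0, 2.0, 2.0, 3.0, 4.0])
        r = ba.heading_coherence(x, np.zeros_like(x), smooth_window=1)
        assert r == pytest.approx(1.0)

    def test_isotropic_random_walk_matches_rayleigh_expectation(self):
        # unsmoothed coherence of n iid uniform headings: E[R] ~ sqrt(pi)/(2 sqrt(n))
        rng = np.random.default_rng(2)
        n = 60
        rs = []
        for _ in range(300):
            th = rng.uniform(0, 2 * np.pi, n + 1)
            x = np.concatenate([[0], np.cumsum(np.cos(th))])
            y = np.concatenate([[0], np.cumsum(np.sin(th))])
            rs.append(ba.heading_coherence(x, y, smooth_window=1))
        expected = np.sqrt(np.pi) / (2 * np.sqrt(n + 1))
        assert np.mean(rs) == pytest.approx(expected, rel=0.15)

    def test_all_static_rejected(self):
        with pytest.raises(ValueError):
            ba.heading_coherence(np.zeros(30), np.zeros(30))


class TestClusterStates:
    def test_two_point_masses_recovered_exactly(self):
        v = np.array([90.0] * 12 + [30.0] * 8)
        r = np.array([0.9] * 12 + [0.1] * 8)
        res = ba.cluster_states(v, r, seed=0)
        assert res.proportions[FAST] == pytest.approx(0.6)
        assert res.speed_mean[FAST] == pytest.approx(90.0)
        assert res.speed_mean[SLOW] == pytest.approx(30.0)
        assert (res.labels[:12] == FAST).all() and (res.labels[12:] == SLOW).all()

    def test_semantic_labels_invariant_to_component_permutation(self):
        rng = np.random.default_rng(3)
        v = np.concatenate([rng.normal(90, 5, 40), rng.normal(30, 5, 40)])
        r = np.concatenate([rng.normal(0.9, 0.02, 40), rng.normal(0.1, 0.02, 40)])
        labels = [ba.cluster_states(v, r, seed=s).labels for s in (0, 1, 2, 7)]
        for lab in labels[1:]:
            assert (lab == labels[0]).all()

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(10, 100, 30)
        r = rng.uniform(0, 1, 30)
        res = ba.cluster_states(v, r, seed=0)
        assert res.proportions[FAST] + res.proportions[SLOW] == pytest.approx(1.0)

    def test_single_point_mass_flags_degenerate(self):
        import warnings

        v = np.full(20, 50.0)
        r = np.full(20, 0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ba.cluster_states(v, r, seed=0)
        assert res.degenerate_warning

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            ba.cluster_states(np.ones(5), np.ones(5), seed=0)


class TestStateDependence:
    def _trials(self, deltas_v, deltas_r, label):
        return [TrialState(50.0, 0.5, 50.0 + dv, 0.5 + dr, label)
                for dv, dr in zip(deltas_v, deltas_r)]

    def test_all_zero_deltas_give_t0_p1(self):
        trials = self._trials([0.0] * 6, [0.0] * 6, FAST)
        df = ba.state_dependence(trials)
        row = df[(df.cluster == FAST) & (df.feature == "speed")].iloc[0]
        assert row.t == 0.0 and row.p == 1.0 and not row.degenerate

    def test_constant_nonzero_deltas_flagged_degenerate(self):
        trials = self._trials([-1.0] * 4, [0.1, 0.2, -0.1, 0.3], FAST)
        df = ba.state_dependence(trials)
        row = df[(df.cluster == FAST) & (df.feature == "speed")].iloc[0]
        assert row.degenerate and np.isnan(row.t)

    def test_constructed_slowing_effect_gives_negative_t(self):
        rng = np.random.default_rng(6)
        fast = self._trials(rng.normal(-30, 5, 20), rng.normal(-0.3, 0.05, 20), FAST)
        slow = self._trials(rng.normal(0, 5, 10), rng.normal(0.4, 0.05, 10), SLOW)
        df = ba.state_dependence(fast + slow)
        f_speed = df[(df.cluster == FAST) & (df.feature == "speed")].iloc[0]
        assert f_speed.mean_delta < 0 and f_speed.t < 0 and f_speed.p < 0.01
        s_coh = df[(df.cluster == SLOW) & (df.feature == "coherence")].iloc[0]
        assert s_coh.t > 0

    def test_small_cluster_statistics_omitted(self):
        trials = self._trials([1.0], [0.1], SLOW) + self._trials(
            [0.5, -0.5, 1.0], [0.0, 0.1, 0.2], FAST)
        df = ba.state_dependence(trials)
        assert not ((df.cluster == SLOW) & (df.feature == "speed")).any()


class TestFootprintHistogram:
    def test_static_paw_occupies_single_bin(self):
        h, _, _ = ba.footprint_histogram(np.full(50, 5.0), np.full(50, 7.0), bins=10)
        assert (h > 0).sum() == 1
        assert h.max() == 50

    def test_gait_dwell_maxima_match_stance_count(self):
        # short single-pass bout so successive footprints do not overlap
        pose = rig.simulate_gait(rig.GaitParams(), 5.0, seed=9)
        traj = ba.preprocess(pose, "left_hindpaw_mid", jump_px=np.inf)
        res = ba.gait_phases(traj)
        n_stances = len(res.stance_durations_ms)
        assert n_stances >= 5
        h, _, _ = ba.footprint_histogram(traj.x, traj.y,
                                         bins=[int(np.ptp(traj.x) / 10), 3])
        n_maxima = ba.count_dwell_maxima(h, min_count=4)
        assert abs(n_maxima - n_stances) <= 3

    def test_uniform_positions_have_no_hotspot(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 100, 10000)
        y = rng.uniform(0, 100, 10000)
        h, _, _ = ba.footprint_histogram(x, y, bins=10)
        assert h.max() <= 3 * 10000 / 100
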