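"""End-to-end parameter-recovery workflows on the virtual rig.

Each workflow simulates the relevant study conditions from scratch —
calibration rasters, gait sessions, response-latency trials, two-state
movement trials — runs the corresponding analysis pipeline, and reports the
recovered quantity with its sampling uncertainty. These are the package's
reproducibility entry points (used by ``scripts/acceptance.py`` and the
test suite) and convenient templates for configuring real sessions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import behavior_analysis as ba
from . import calibration as cal
from . import virtual_rig as rig

__all__ = [
    "calibration_heldout_mae",
    "gait_recovery",
    "static_fraction_by_preset",
    "me_latency_recovery",
    "pose_latency_recovery",
    "state_cluster_recovery",
]


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _inset(bounds: tuple[float, float], frac: float = 0.03) -> tuple[float, float]:
    lo, hi = bounds
    pad = frac * (hi - lo)
    return (lo + pad, hi - pad)


@dataclass(frozen=True)
class CalibrationRecovery:
    mae_px: float
    mae_mm: float
    n_heldout: int
    n_raster: int
    fit_residual_px: float


def calibration_heldout_mae(
    seed: int,
    nx: int = 100,
    ny: int = 100,
    degree: int = 3,
    distortion_px: float = 20.0,
    noise_sd_px: float = 0.8,
    heldout_stride: int = 3,
    scale_mm_per_px: float = 0.45,
) -> CalibrationRecovery:
    """Simulated-rig calibration with a held-out interleaved grid.

    Simulates optics with a smooth degree-2 distortion (bounded well below
    5% of the platform width) and sub-pixel spot noise, acquires the default
    100 x 100 raster over the inner 94% of the voltage range, fits the
    calibration surfaces, and measures the mean Euclidean error between
    held-out target pixels (midpoints between raster lines) and the spots
    realized by steering with the fitted map.
    """
    r_optics, r_obs, r_eval = _child_rngs(seed, 3)
    optics = rig.make_distorted_optics(r_optics, magnitude_px=distortion_px,
                                       noise_sd_px=noise_sd_px)
    vb = optics.voltage_bounds
    bounds = (_inset(vb[0]), _inset(vb[1]))
    raster = cal.make_raster(nx, ny, bounds)
    obs = rig.acquire_raster_observations(raster, optics, r_obs)
    cmap = cal.fit_map(obs, degree=degree)

    vxs = np.linspace(*bounds[0], nx)
    vys = np.linspace(*bounds[1], ny)
    mx = ((vxs[:-1] + vxs[1:]) / 2)[::heldout_stride]
    my = ((vys[:-1] + vys[1:]) / 2)[::heldout_stride]
    MX, MY = np.meshgrid(mx, my)
    v_mid = np.column_stack([MX.ravel(), MY.ravel()])
    targets = rig.optics_forward(v_mid, optics, noise=False)
    result = cal.evaluate_map(
        cmap, targets,
        forward=lambda v: rig.optics_forward(v, optics, seed=r_eval, noise=True),
        scale_mm_per_px=scale_mm_per_px,
    )
    return CalibrationRecovery(
        mae_px=result.mae_px,
        mae_mm=result.mae_mm,
        n_heldout=result.n,
        n_raster=len(raster),
        fit_residual_px=cmap.residual_mae_px,
    )


@dataclass(frozen=True)
class GaitRecovery:
    stance_mean_ms: float
    stance_sem_ms: float
    n_stance: int
    swing_mean_ms: float
    swing_sem_ms: float
    n_swing: int


def gait_recovery(
    seed: int,
    n_sessions: int = 10,
    duration_s: float = 60.0,
    fps: float = 30.0,
    params: rig.GaitParams | None = None,
) -> GaitRecovery:
    """Pooled stance/swing durations recovered from simulated locomotion.

    Runs the gait generator at its defaults for ``n_sessions`` sessions,
    segments both hind-paw trajectories, and pools interior stance/swing
    segment durations. The tracking-jump filter is disabled for paw
    trajectories: a swinging paw legitimately travels tens of pixels per
    frame, unlike the slow keypoints the jump filter is designed for.
    """
    params = params or rig.GaitParams()
    stance, swing = [], []
    for r in _child_rngs(seed, n_sessions):
        pose = rig.simulate_gait(params, duration_s, fps=fps, seed=r)
        for part in ("left_hindpaw_mid", "right_hindpaw_mid"):
            traj = ba.preprocess(pose, part, jump_px=np.inf)
            res = ba.gait_phases(traj)
            stance.append(res.stance_durations_ms)
            swing.append(res.swing_durations_ms)
    st = np.concatenate(stance)
    sw = np.concatenate(swing)
    return GaitRecovery(
        stance_mean_ms=float(st.mean()),
        stance_sem_ms=float(st.std(ddof=1) / np.sqrt(st.size)),
        n_stance=int(st.size),
        swing_mean_ms=float(sw.mean()),
        swing_sem_ms=float(sw.std(ddof=1) / np.sqrt(sw.size)),
        n_swing=int(sw.size),
    )


def static_fraction_by_preset(seed: int, duration_s: float = 60.0) -> dict[str, float]:
    """Fraction of static hind-paw frames for each body-speed preset."""
    out: dict[str, float] = {}
    rngs = _child_rngs(seed, len(rig.SPEED_PRESETS))
    for (name, params), r in zip(rig.SPEED_PRESETS.items(), rngs):
        pose = rig.simulate_gait(params, duration_s, seed=r)
        fracs = []
        for part in ("left_hindpaw_mid", "right_hindpaw_mid"):
            traj = ba.preprocess(pose, part, jump_px=np.inf)
            res = ba.gait_phases(traj)
            fracs.append(np.mean(res.static_labels))
        out[name] = float(np.mean(fracs))
    return out


@dataclass(frozen=True)
class LatencyRecovery:
    mean_s: float
    sem_s: float
    n_responding: int
    n_trials: int
    generated_mean_s: float


def me_latency_recovery(seed: int, n_trials: int = 200) -> LatencyRecovery:
    """Mean latency recovered by the motion-energy pipeline on synthetic
    trials whose onsets realize the thermal-trial latency distribution."""
    traces, nominal, lats = rig.generate_me_response_trials(n_trials, seed=seed)
    measured = []
    for i in range(n_trials):
        r = ba.me_latency(traces[i], nominal)
        if r.responded:
            measured.append(r.latency_s)
    m = np.asarray(measured)
    return LatencyRecovery(
        mean_s=float(m.mean()),
        sem_s=float(m.std(ddof=1) / np.sqrt(m.size)),
        n_responding=int(m.size),
        n_trials=n_trials,
        generated_mean_s=float(lats.mean()),
    )


def pose_latency_recovery(seed: int, n_trials: int = 200) -> LatencyRecovery:
    """Mean latency recovered by the pose pipeline on synthetic withdrawal
    trials realizing the strongest-stimulus latency distribution."""
    trials, lats = rig.generate_pose_response_trials(n_trials, seed=seed)
    measured = []
    for tr in trials:
        r = ba.pose_latency(tr["x"], tr["y"], tr["likelihood"], tr["timestamps"],
                            tr["stim_time"])
        if r.responded:
            measured.append(r.latency_s)
    m = np.asarray(measured)
    return LatencyRecovery(
        mean_s=float(m.mean()),
        sem_s=float(m.std(ddof=1) / np.sqrt(m.size)),
        n_responding=int(m.size),
        n_trials=n_trials,
        generated_mean_s=float(lats.mean()),
    )


@dataclass(frozen=True)
class StateClusterRecovery:
    fast_proportion_pct: float
    fast_speed_mean: float
    fast_speed_sem: float
    slow_speed_mean: float
    slow_speed_sem: float
    fast_coherence_mean: float
    slow_coherence_mean: float
    n_trials: int
    n_fast: int
    n_slow: int
    ground_truth_agreement: float


def state_cluster_recovery(seed: int, n_trials: int = 116,
                           cluster_seed: int = 0) -> StateClusterRecovery:
    """Two-state mixture recovery on synthetic pre-stimulation trials.

    Generates trials at the published two-state parameters, measures
    pre-window speed and heading coherence with the analysis pipelines, fits
    the seeded two-component Gaussian mixture, and reports the recovered
    cluster proportions and per-cluster means.
    """
    trials, labels = rig.generate_state_trials(rig.PUBLISHED_STATE_PARAMS, n_trials, seed=seed)
    speeds, cohs = [], []
    for tr in trials:
        n_pre = tr.n_frames // 2
        pre = tr.slice(0, n_pre)
        traj = ba.preprocess(pre, "tail_base", jump_px=np.inf)
        _, v_mm = ba.speed(traj)
        speeds.append(float(np.nanmean(v_mm)))
        cohs.append(ba.heading_coherence(traj.x, traj.y))
    speeds = np.asarray(speeds)
    cohs = np.asarray(cohs)
    res = ba.cluster_states(speeds, cohs, seed=cluster_seed)
    fast = res.labels == ba.FAST
    gt_fast = labels == 0
    agreement = max(float(np.mean(fast == gt_fast)), float(np.mean(fast != gt_fast)))
    n_fast = int(fast.sum())
    n_slow = int((~fast).sum())
    return StateClusterRecovery(
        fast_proportion_pct=100.0 * res.proportions[ba.FAST],
        fast_speed_mean=res.speed_mean[ba.FAST],
        fast_speed_sem=res.speed_sd[ba.FAST] / np.sqrt(max(n_fast, 1)),
        slow_speed_mean=res.speed_mean[ba.SLOW],
        slow_speed_sem=res.speed_sd[ba.SLOW] / np.sqrt(max(n_slow, 1)),
        fast_coherence_mean=res.coherence_mean[ba.FAST],
        slow_coherence_mean=res.coherence_mean[ba.SLOW],
        n_trials=n_trials,
        n_fast=n_fast,
        n_slow=n_slow,
        ground_truth_agreement=agreement,
    )
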