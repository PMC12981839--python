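"""Closed-loop trigger, targeting and hit adjudication.

The control loop evaluates a stillness rule on a trailing window of the
target keypoint — the keypoint must stay within a positional dispersion
``v`` (a standard deviation in pixels, strict ``sd < v``) with likelihood
strictly above ``l`` throughout a period of at least ``t`` seconds — and,
when the refractory interval has elapsed, converts the keypoint to mirror
voltages through the calibration map, samples the processing + actuation
delay, and realizes the laser spot through the optics ground truth. Because
targeting uses the keypoint at the trigger frame, hits degrade when the paw
moves during the delay; adjudication scores hits, cross-paw confusions and
targeting error against the ground-truth pose.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import PoseSeries, EventRecord
from .calibration import CalibrationMap, predict_voltage
from .virtual_rig import OpticsModel, LatencyModel, optics_forward, _require_seed
from . import behavior_analysis as ba

__all__ = [
    "TriggerParams",
    "PulseSpec",
    "Protocol",
    "StimulusEvent",
    "SessionLog",
    "WindowTooShortError",
    "stillness_trigger",
    "run_session",
    "adjudicate",
]

PAW_PARTS = ("left_forepaw", "right_forepaw", "left_hindpaw_mid", "right_hindpaw_mid")


class WindowTooShortError(ValueError):
    """The pose window does not span the required stillness duration."""


@dataclass(frozen=True)
class TriggerParams:
    """User-defined stillness trigger: dispersion v (px, as a standard
    deviation), duration t (s), likelihood floor l, refractory interval."""

    v_px: float = 1.0
    t_s: float = 2.0
    l_min: float = 0.8
    refractory_s: float = 0.5
    target: str = "left_hindpaw_mid"

    def __post_init__(self) -> None:
        if self.v_px <= 0 or self.t_s <= 0:
            raise ValueError("v and t must be positive")
        if not (0 < self.l_min <= 1):
            raise ValueError("l must lie in (0, 1]")
        if self.refractory_s < 0:
            raise ValueError("refractory must be non-negative")


@dataclass(frozen=True)
class PulseSpec:
    duration_ms: float
    intensity_mw_mm2: float = 40.0
    train_hz: float | None = None


@dataclass(frozen=True)
class Protocol:
    """Session protocol: pulse spec, refractory, and whether the stillness
    rule gates firing (characterization sessions fire on any confidently
    tracked frame)."""

    pulse: PulseSpec
    refractory_s: float = 0.5
    require_still: bool = True
    footprint_radius_px: float = 5.0


@dataclass
class StimulusEvent:
    trigger_frame: int
    trigger_time_s: float
    fire_time_s: float
    target_xy: tuple[float, float]
    voltages: tuple[float, float]
    spot_xy: tuple[float, float]
    pulse: PulseSpec
    hit: bool
    confusion: bool
    error_px: float

    def __post_init__(self) -> None:
        if self.fire_time_s <= self.trigger_time_s:
            raise ValueError("fire time must follow trigger time")
        if self.confusion and self.hit:
            raise ValueError("a confused stimulus cannot be a hit on the intended target")


@dataclass
class SessionLog:
    pose: PoseSeries
    stimuli: list[StimulusEvent]
    events: list[EventRecord]
    config: dict
    seed: int | None


def stillness_trigger(window: PoseSeries, params: TriggerParams) -> bool:
    """True iff the target keypoint was still throughout the window.

    Stillness: population standard deviation of x and of y strictly below
    ``v`` and likelihood strictly above ``l`` at every frame. Windows
    spanning less than ``t`` seconds are refused (not treated as False).
    """
    span = (window.n_frames - 1) / window.fps
    if span + 1e-9 < params.t_s:
        raise WindowTooShortError(
            f"window spans {span:.3f} s < required stillness duration {params.t_s} s"
        )
    x, y, lik = window.part(params.target)
    if np.any(lik <= params.l_min):
        return False
    return bool(np.std(x) < params.v_px and np.std(y) < params.v_px)


def _pose_at_time(pose: PoseSeries, part_idx: int, t: float) -> tuple[float, float]:
    """Ground-truth keypoint position at an arbitrary time (linear interp)."""
    ts = pose.timestamps
    x = float(np.interp(t, ts, pose.x[:, part_idx]))
    y = float(np.interp(t, ts, pose.y[:, part_idx]))
    return x, y


def run_session(
    pose: PoseSeries,
    cmap: CalibrationMap,
    optics: OpticsModel,
    latency: LatencyModel,
    trigger: TriggerParams,
    protocol: Protocol,
    seed: int | None,
) -> SessionLog:
    """Run the closed-loop control loop over a (simulated) pose stream.

    Per frame the trailing stillness window is evaluated (when the protocol
    requires stillness); an eligible trigger creates a stimulus with a
    sampled processing + actuation delay, targets the keypoint *from the
    trigger frame*, and realizes the spot through the optics at fire time.
    After each stimulus the stillness window re-arms from the fire frame, so
    a single long still epoch cannot yield a burst. Hits are adjudicated
    against the ground-truth pose at fire time within the paw footprint
    radius; a spot inside a different paw's footprint counts as confusion.
    """
    rng = _require_seed(seed)
    fps = pose.fps
    w = int(np.ceil(trigger.t_s * fps)) + 1  # frames spanning >= t seconds
    target_idx = pose.part_index(trigger.target)
    paw_idx = {p: pose.part_index(p) for p in PAW_PARTS if p in pose.bodyparts}

    # vectorized trailing-window statistics for the target keypoint
    sx = pd.Series(pose.x[:, target_idx])
    sy = pd.Series(pose.y[:, target_idx])
    roll_sd_x = sx.rolling(w).std(ddof=0).to_numpy()
    roll_sd_y = sy.rolling(w).std(ddof=0).to_numpy()
    roll_min_lik = pd.Series(pose.likelihood[:, target_idx]).rolling(w).min().to_numpy()

    stimuli: list[StimulusEvent] = []
    events: list[EventRecord] = []
    last_fire = -np.inf
    rearm_frame = 0
    refractory = max(protocol.refractory_s, trigger.refractory_s)

    for i in range(pose.n_frames):
        t = pose.timestamps[i]
        if t - last_fire <= refractory:
            continue
        if protocol.require_still:
            if i < w - 1 or (i - (w - 1)) < rearm_frame:
                continue
            ok = (
                roll_min_lik[i] > trigger.l_min
                and roll_sd_x[i] < trigger.v_px
                and roll_sd_y[i] < trigger.v_px
            )
        else:
            ok = pose.likelihood[i, target_idx] > trigger.l_min
        if not ok:
            continue

        kp = (float(pose.x[i, target_idx]), float(pose.y[i, target_idx]))
        volts = predict_voltage(cmap, np.asarray(kp), clamp=True)
        delay = latency.sample_delay_s(rng)
        fire_t = t + delay
        spot = optics_forward(volts, optics, seed=rng, noise=True)
        fire_t_clamped = min(fire_t, pose.timestamps[-1])

        hit = False
        confusion = False
        err = np.inf
        target_at_fire = _pose_at_time(pose, target_idx, fire_t_clamped)
        err = float(np.hypot(spot[0] - target_at_fire[0], spot[1] - target_at_fire[1]))
        hit = err <= protocol.footprint_radius_px
        if not hit:
            for part, j in paw_idx.items():
                if j == target_idx:
                    continue
                px, py = _pose_at_time(pose, j, fire_t_clamped)
                if np.hypot(spot[0] - px, spot[1] - py) <= protocol.footprint_radius_px:
                    confusion = True
                    break

        ev = StimulusEvent(
            trigger_frame=i,
            trigger_time_s=float(t),
            fire_time_s=float(fire_t),
            target_xy=kp,
            voltages=(float(volts[0]), float(volts[1])),
            spot_xy=(float(spot[0]), float(spot[1])),
            pulse=protocol.pulse,
            hit=bool(hit),
            confusion=bool(confusion),
            error_px=err,
        )
        stimuli.append(ev)
        events.append(EventRecord(float(t), "trigger", {"frame": i, "target": trigger.target}))
        events.append(EventRecord(float(fire_t), "stimulus", {
            "frame": i, "hit": bool(hit), "confusion": bool(confusion),
            "error_px": err, "x": spot[0], "y": spot[1],
        }))
        last_fire = fire_t
        # re-arm: the stillness window restarts from the fire frame
        rearm_frame = int(np.searchsorted(pose.timestamps, fire_t))

    return SessionLog(
        pose=pose,
        stimuli=stimuli,
        events=events,
        config={"trigger": asdict(trigger), "protocol": {
            "pulse": asdict(protocol.pulse),
            "refractory_s": protocol.refractory_s,
            "require_still": protocol.require_still,
            "footprint_radius_px": protocol.footprint_radius_px,
        }},
        seed=seed if isinstance(seed, int) else None,
    )


def adjudicate(
    stimuli: Sequence[StimulusEvent],
    pose: PoseSeries,
    footprint_radius_px: float = 5.0,
    scale_mm_per_px: float = 0.45,
) -> dict:
    """Hit-accuracy table by body-speed category, confusion counts, and the
    mean targeting error over hits.

    Body speed categories come from the tail-base speed trace at each
    stimulus's trigger frame. Raises if a stimulus falls outside the pose
    time range.
    """
    stimuli = list(stimuli)
    if any(s.trigger_time_s < pose.timestamps[0] or s.trigger_time_s > pose.timestamps[-1]
           for s in stimuli):
        raise ValueError("stimulus outside the pose time range")
    traj = ba.preprocess(pose, "tail_base", likelihood_min=0.0,
                         jump_px=np.inf, scale_mm_per_px=scale_mm_per_px)
    v_px, _ = ba.speed(traj)
    cats = ba.categorize_speed(v_px)

    rows = []
    for cat in ba.SPEED_CATEGORIES:
        sel = [s for s in stimuli if cats[s.trigger_frame] == cat]
        if not sel:
            continue
        hits = sum(s.hit for s in sel)
        conf = sum(s.confusion for s in sel)
        rows.append({"category": cat, "n": len(sel), "hits": hits,
                     "hit_fraction": hits / len(sel), "confusions": conf})
    table = pd.DataFrame(rows)
    hit_errors = np.array([s.error_px for s in stimuli if s.hit])
    return {
        "by_category": table,
        "n": len(stimuli),
        "n_hits": int(sum(s.hit for s in stimuli)),
        "n_confusions": int(sum(s.confusion for s in stimuli)),
        "targeting_mae_px": float(hit_errors.mean()) if hit_errors.size else np.nan,
        "targeting_mae_mm": float(hit_errors.mean() * scale_mm_per_px) if hit_errors.size else np.nan,
    }
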