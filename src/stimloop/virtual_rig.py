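"""Virtual rig: hardware stand-ins for animals, camera, optics and delays.

Everything the physical system provides is emulated here so the control loop
and the analysis pipelines can run end to end at a desk:

* a gait-realistic mouse generator (alternating stance/swing hind paws, a
  tail base advancing at the body speed),
* a frame renderer turning keypoints into grayscale blobs for motion-energy
  computations,
* an optics forward model (voltage -> laser-spot pixel with a smooth
  nonlinear distortion and sub-pixel observation noise) — the ground truth
  the calibration module must invert,
* a closed-loop latency model (processing + actuation delays),
* generators for two-state movement trajectories and for response-latency
  trials with a prescribed latency distribution.

All stochastic operations require an explicit seed and are bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .core_io import PoseSeries, FrameStack, DEFAULT_BODYPARTS

__all__ = [
    "GaitParams",
    "SPEED_PRESETS",
    "OpticsModel",
    "LatencyModel",
    "MovementStateParams",
    "StateTrajectoryParams",
    "PUBLISHED_STATE_PARAMS",
    "simulate_gait",
    "render_frames",
    "optics_forward",
    "make_distorted_optics",
    "acquire_raster_observations",
    "generate_state_trials",
    "generate_me_response_trials",
    "generate_pose_response_trials",
]


def _require_seed(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("stochastic operations require an explicit seed")
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Gait simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaitParams:
    """Stance/swing timing statistics and body speed for the gait generator.

    Defaults reproduce the locomotion regime in which hind paws dwell
    ~350 +/- 44 ms in stance and move ~100 +/- 1 ms in swing, with left and
    right hind paws half a cycle out of phase.
    """

    stance_mean_ms: float = 350.0
    stance_sd_ms: float = 44.0
    swing_mean_ms: float = 100.0
    swing_sd_ms: float = 1.0
    phase_offset_lr: float = 0.5
    body_speed_px_s: float = 170.0
    stride_length_px: float | None = None  # derived from speed x cycle if None
    base_likelihood: float = 0.95
    dropout_fraction: float = 0.0
    dropout_likelihood: float = 0.3
    obs_noise_sd_px: float = 0.0

    def __post_init__(self) -> None:
        if min(self.stance_mean_ms, self.swing_mean_ms) <= 0:
            raise ValueError("stance/swing durations must be positive")
        if not (0 <= self.phase_offset_lr < 1):
            raise ValueError("phase offset must lie in [0, 1)")
        if self.body_speed_px_s < 0:
            raise ValueError("body speed must be non-negative")


#: Body-speed presets spanning the four locomotion categories. Stance
#: duration shortens as body speed rises, reproducing the observed decline
#: in the fraction of static hind-paw frames from stationary to high speed.
SPEED_PRESETS: dict[str, GaitParams] = {
    "stationary": GaitParams(body_speed_px_s=0.0),
    "low": GaitParams(body_speed_px_s=70.0, stance_mean_ms=800.0, stance_sd_ms=80.0),
    "medium": GaitParams(body_speed_px_s=170.0, stance_mean_ms=350.0, stance_sd_ms=44.0),
    "high": GaitParams(body_speed_px_s=300.0, stance_mean_ms=150.0, stance_sd_ms=20.0),
}


def _stochastic_round_frames(duration_ms: float, fps: float, rng: np.random.Generator) -> int:
    """Whole-frame duration with an unbiased stochastic rounding."""
    frames = duration_ms * fps / 1000.0
    base = int(np.floor(frames))
    k = base + int(rng.random() < (frames - base))
    return max(1, k)


def _triangle_wave_positions(n: int, fps: float, speed: float, lo: float, hi: float,
                             start: float) -> tuple[np.ndarray, np.ndarray]:
    """1-D position bouncing between lo and hi at constant |speed|."""
    if speed == 0:
        return np.full(n, start), np.ones(n)
    span = hi - lo
    t = np.arange(n) / fps
    # phase in a 2*span period, offset so the wave starts at `start` moving +
    u = (speed * t + (start - lo)) % (2 * span)
    pos = np.where(u <= span, lo + u, hi - (u - span))
    direction = np.where(u <= span, 1.0, -1.0)
    return pos, direction


# lateral lanes and fore/aft offsets (px) of each body part relative to the
# body axis; paw x-offsets are applied along the direction of travel
_PART_LAYOUT = {
    "snout": (35.0, 0.0),
    "left_forepaw": (20.0, 18.0),
    "right_forepaw": (20.0, -18.0),
    "left_hindpaw_mid": (-25.0, 22.0),
    "right_hindpaw_mid": (-25.0, -22.0),
    "tail_base": (-40.0, 0.0),
}
_PAW_PHASES = {
    "left_hindpaw_mid": 0.0,
    "right_hindpaw_mid": None,  # set from phase_offset_lr
    "left_forepaw": None,  # diagonal couplet with the right hind paw
    "right_forepaw": 0.0,
}


def simulate_gait(
    params: GaitParams,
    duration_s: float,
    fps: float = 30.0,
    seed: int | np.random.Generator | None = None,
    frame_size: tuple[int, int] = (1100, 1100),
) -> PoseSeries:
    """Simulate a walking mouse as a keypoint pose series.

    The body (tail base) advances at ``body_speed_px_s`` along a lane,
    bouncing off the arena margins. Each paw alternates between stance
    (planted exactly at a fixed pixel) and swing (linear travel to the next
    plant, landing on it at the final swing frame). Stance and swing
    durations are drawn per cycle from the configured normal distributions
    and quantized to whole frames by unbiased stochastic rounding, so
    run-length based segmentation recovers the configured means. With zero
    body speed every paw is static for the whole series.
    """
    if duration_s < 1.0:
        raise ValueError("duration must be at least 1 s")
    if fps < 10:
        raise ValueError("fps must be at least 10")
    rng = _require_seed(seed)
    n = int(round(duration_s * fps))
    w, h = frame_size
    margin = 80.0
    cy = h / 2.0
    body_x, direction = _triangle_wave_positions(
        n, fps, params.body_speed_px_s, margin, w - margin, w / 2.0
    )

    parts = DEFAULT_BODYPARTS
    x = np.empty((n, len(parts)))
    y = np.empty((n, len(parts)))

    cycle_ms = params.stance_mean_ms + params.swing_mean_ms
    phases = dict(_PAW_PHASES)
    phases["right_hindpaw_mid"] = params.phase_offset_lr
    phases["left_forepaw"] = params.phase_offset_lr

    for j, part in enumerate(parts):
        fore_aft, lateral = _PART_LAYOUT[part]
        lane = cy + lateral
        if part in ("snout", "tail_base"):
            x[:, j] = np.clip(body_x + fore_aft * direction, 1.0, w - 2.0)
            y[:, j] = lane
            continue
        if params.body_speed_px_s == 0:
            x[:, j] = body_x[0] + fore_aft
            y[:, j] = lane
            continue
        # paw: alternate stance (hold) and swing (linear travel to new plant)
        pos = np.empty(n)
        cur = 0
        plant = body_x[0] + fore_aft * direction[0]
        phase = phases[part]
        first_stance_ms = max(
            params.swing_mean_ms,
            rng.normal(params.stance_mean_ms, params.stance_sd_ms) - phase * cycle_ms,
        )
        first = True
        while cur < n:
            stance_ms = first_stance_ms if first else rng.normal(
                params.stance_mean_ms, params.stance_sd_ms
            )
            first = False
            k = _stochastic_round_frames(stance_ms, fps, rng)
            k = min(k, n - cur)
            pos[cur : cur + k] = plant
            cur += k
            if cur >= n:
                break
            m = _stochastic_round_frames(
                rng.normal(params.swing_mean_ms, params.swing_sd_ms), fps, rng
            )
            m = min(m, n - cur)
            land = min(cur + m - 1, n - 1)
            new_plant = body_x[land] + fore_aft * direction[land]
            steps = (np.arange(1, m + 1)) / m
            pos[cur : cur + m] = plant + steps * (new_plant - plant)
            cur += m
            plant = new_plant
        x[:, j] = np.clip(pos, 1.0, w - 2.0)
        y[:, j] = lane

    if params.obs_noise_sd_px > 0:
        x += rng.normal(0.0, params.obs_noise_sd_px, size=x.shape)
        y += rng.normal(0.0, params.obs_noise_sd_px, size=y.shape)
        x = np.clip(x, 0.0, w - 1.0)
        y = np.clip(y, 0.0, h - 1.0)

    lik = np.full((n, len(parts)), params.base_likelihood)
    if params.dropout_fraction > 0:
        drop = rng.random((n, len(parts))) < params.dropout_fraction
        lik[drop] = params.dropout_likelihood

    return PoseSeries(bodyparts=parts, x=x, y=y, likelihood=lik, fps=fps,
                      frame_size=frame_size)


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------


def render_frames(
    pose: PoseSeries,
    blob_sd_px: float = 3.0,
    background_noise_sd: float = 0.0,
    blob_amplitude: float = 200.0,
    seed: int | np.random.Generator | None = None,
) -> FrameStack:
    """Render each body part as an isotropic intensity blob per frame.

    Frames are 8-bit grayscale of the pose's ``frame_size``. With zero
    background noise, a stationary pose yields identical frames, so any
    motion energy after noise suppression comes from movement alone.
    """
    if blob_sd_px <= 0:
        raise ValueError("blob_sd must be positive")
    w, h = pose.frame_size
    if np.any(pose.x < 0) or np.any(pose.x >= w) or np.any(pose.y < 0) or np.any(pose.y >= h):
        raise ValueError("pose coordinates exceed the frame size")
    rng = _require_seed(seed) if background_noise_sd > 0 else None
    n = pose.n_frames
    frames = np.zeros((n, h, w), dtype=float)
    reach = int(np.ceil(3 * blob_sd_px))
    for i in range(n):
        for j in range(len(pose.bodyparts)):
            if pose.likelihood[i, j] <= 0:
                continue
            cx, cy = pose.x[i, j], pose.y[i, j]
            x0, x1 = max(0, int(cx) - reach), min(w, int(cx) + reach + 1)
            y0, y1 = max(0, int(cy) - reach), min(h, int(cy) + reach + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            g = blob_amplitude * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * blob_sd_px**2)
            )
            frames[i, y0:y1, x0:x1] = np.maximum(frames[i, y0:y1, x0:x1], g)
        if rng is not None:
            frames[i] += rng.normal(0.0, background_noise_sd, size=(h, w))
    return FrameStack(
        frames=np.clip(frames, 0, 255).astype(np.uint8),
        timestamps=pose.timestamps.copy(),
        fps=pose.fps,
    )


# ---------------------------------------------------------------------------
# Optics forward model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticsModel:
    """Ground-truth voltage -> laser-spot-pixel map with smooth distortion.

    The linear part maps voltages to pixels through a per-axis gain (volts
    per pixel); a degree-``distortion_degree`` polynomial perturbation in
    normalized pixel coordinates models the nonlinear optics, bounded below
    5% of the platform width so the map stays injective. ``noise_sd_px``
    models sub-pixel spot-detection noise. Distortion coefficients follow
    the monomial order "by total degree, x-exponent increasing within each
    degree": for degree 2 that is 1, v, u, v^2, u*v, u^2 with (u, v) the
    pixel coordinates normalized to [-1, 1].
    """

    gain_v_per_px: tuple[float, float] = (0.01, 0.01)
    offset_v: tuple[float, float] = (0.0, 0.0)
    distortion_degree: int = 2
    distortion_coeff_x: tuple[float, ...] = ()
    distortion_coeff_y: tuple[float, ...] = ()
    noise_sd_px: float = 0.8
    platform_px: tuple[float, float] = (1100.0, 1100.0)

    def __post_init__(self) -> None:
        # injectivity guard: bound the distortion magnitude on a dense grid
        if self.distortion_coeff_x or self.distortion_coeff_y:
            gx = np.linspace(0, self.platform_px[0], 25)
            gy = np.linspace(0, self.platform_px[1], 25)
            XX, YY = np.meshgrid(gx, gy)
            pts = np.column_stack([XX.ravel(), YY.ravel()])
            d = self._distortion(pts)
            limit = 0.05 * self.platform_px[0]
            if np.max(np.abs(d)) >= limit:
                raise ValueError(
                    f"distortion magnitude {np.max(np.abs(d)):.1f} px exceeds 5% of "
                    f"platform width ({limit:.1f} px); forward map may not be injective"
                )

    @property
    def voltage_bounds(self) -> tuple[tuple[float, float], tuple[float, float]]:
        w, h = self.platform_px
        gx, gy = self.gain_v_per_px
        ox, oy = self.offset_v
        bx = sorted((ox, ox + gx * w))
        by = sorted((oy, oy + gy * h))
        return ((bx[0], bx[1]), (by[0], by[1]))

    def _exponents(self) -> list[tuple[int, int]]:
        deg = self.distortion_degree
        return [(i, j) for total in range(deg + 1) for i in range(total + 1) for j in [total - i]]

    def _distortion(self, linear_px: np.ndarray) -> np.ndarray:
        if not (self.distortion_coeff_x or self.distortion_coeff_y):
            return np.zeros_like(linear_px)
        w, h = self.platform_px
        u = 2 * linear_px[:, 0] / w - 1
        v = 2 * linear_px[:, 1] / h - 1
        basis = np.column_stack([u**i * v**j for i, j in self._exponents()])
        cx = np.asarray(self.distortion_coeff_x or np.zeros(basis.shape[1]))
        cy = np.asarray(self.distortion_coeff_y or np.zeros(basis.shape[1]))
        return np.column_stack([basis @ cx, basis @ cy])


def optics_forward(
    voltages: np.ndarray | Sequence[float],
    model: OpticsModel,
    seed: int | np.random.Generator | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Laser-spot pixel(s) realized for commanded voltage pair(s).

    Deterministic given the seed. Voltages outside the model's physical
    range are refused, mirroring the galvanometer drivers' limits.
    """
    single = np.asarray(voltages).ndim == 1
    v = np.atleast_2d(np.asarray(voltages, dtype=float))
    (bx0, bx1), (by0, by1) = model.voltage_bounds
    eps = 1e-9
    if (np.any(v[:, 0] < bx0 - eps) or np.any(v[:, 0] > bx1 + eps)
            or np.any(v[:, 1] < by0 - eps) or np.any(v[:, 1] > by1 + eps)):
        raise ValueError(f"voltages outside physical range {model.voltage_bounds}")
    gx, gy = model.gain_v_per_px
    ox, oy = model.offset_v
    linear = np.column_stack([(v[:, 0] - ox) / gx, (v[:, 1] - oy) / gy])
    px = linear + model._distortion(linear)
    if noise and model.noise_sd_px > 0:
        rng = _require_seed(seed)
        px = px + rng.normal(0.0, model.noise_sd_px, size=px.shape)
    return px[0] if single else px


def make_distorted_optics(
    seed: int | np.random.Generator | None,
    magnitude_px: float = 20.0,
    degree: int = 2,
    noise_sd_px: float = 0.8,
    platform_px: tuple[float, float] = (1100.0, 1100.0),
    gain_v_per_px: tuple[float, float] = (0.01, 0.01),
) -> OpticsModel:
    """Random smooth degree-``degree`` distortion scaled to ``magnitude_px``."""
    rng = _require_seed(seed)
    n_terms = (degree + 1) * (degree + 2) // 2
    raw_x = rng.normal(size=n_terms)
    raw_y = rng.normal(size=n_terms)
    gx = np.linspace(0, platform_px[0], 25)
    gy = np.linspace(0, platform_px[1], 25)
    XX, YY = np.meshgrid(gx, gy)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    u = 2 * pts[:, 0] / platform_px[0] - 1
    vv = 2 * pts[:, 1] / platform_px[1] - 1
    exps = [(i, j) for total in range(degree + 1) for i in range(total + 1) for j in [total - i]]
    basis = np.column_stack([u**i * vv**j for i, j in exps])
    raw_mag = max(np.max(np.abs(basis @ raw_x)), np.max(np.abs(basis @ raw_y)))
    s = magnitude_px / raw_mag
    return OpticsModel(
        gain_v_per_px=gain_v_per_px,
        distortion_degree=degree,
        distortion_coeff_x=tuple(raw_x * s),
        distortion_coeff_y=tuple(raw_y * s),
        noise_sd_px=noise_sd_px,
        platform_px=platform_px,
    )


def acquire_raster_observations(
    raster_voltages: np.ndarray,
    model: OpticsModel,
    seed: int | np.random.Generator | None,
    noise: bool = True,
):
    """Realize a raster scan: commanded voltages -> observed spot pixels."""
    from .calibration import RasterObservation

    rng = _require_seed(seed) if noise and model.noise_sd_px > 0 else None
    spots = optics_forward(raster_voltages, model, seed=rng, noise=noise)
    return [
        RasterObservation(voltages=(float(v[0]), float(v[1])), pixel=(float(p[0]), float(p[1])))
        for v, p in zip(np.atleast_2d(raster_voltages), np.atleast_2d(spots))
    ]


# ---------------------------------------------------------------------------
# Latency model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatencyModel:
    """Closed-loop delay model: processing then actuation, truncated at zero.

    Defaults: processing 84 +/- 12 ms (frame grab + pose estimation +
    targeting computation), actuation 3.3 +/- 0.5 ms (galvanometer move +
    laser trigger); the end-to-end delay is ~87 ms.
    """

    processing_mean_ms: float = 84.0
    processing_sd_ms: float = 12.0
    actuation_mean_ms: float = 3.3
    actuation_sd_ms: float = 0.5

    def sample_delay_s(self, rng: np.random.Generator, n: int | None = None) -> np.ndarray | float:
        size = 1 if n is None else n
        proc = _truncated_normal(rng, self.processing_mean_ms, self.processing_sd_ms, size)
        act = _truncated_normal(rng, self.actuation_mean_ms, self.actuation_sd_ms, size)
        total = (proc + act) / 1000.0
        return float(total[0]) if n is None else total


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while np.any(bad):  # rejection; negligible for the default parameters
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out < 0
    return out


# ---------------------------------------------------------------------------
# Two-state movement trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MovementStateParams:
    speed_mean_mm_s: float
    speed_sd_mm_s: float
    coherence_mean: float
    coherence_sd: float
    weight: float

    def __post_init__(self) -> None:
        if self.speed_mean_mm_s <= 0:
            raise ValueError(
                "state speed mean must be positive (coherence is undefined at zero speed)"
            )
        if not (0 <= self.coherence_mean <= 1):
            raise ValueError("coherence target must lie in [0, 1]")


@dataclass(frozen=True)
class StateTrajectoryParams:
    """Mixture of two movement states for pre/post stimulation trials."""

    states: tuple[MovementStateParams, MovementStateParams]
    trial_duration_s: float = 4.0  # 2 s pre + 2 s post
    fps: float = 30.0
    scale_mm_per_px: float = 0.45
    smooth_window: int = 10
    # optional post-stimulation effects per state index:
    # (speed multiplier, coherence target override or None)
    post_effects: tuple[tuple[float, float | None], ...] | None = None

    def __post_init__(self) -> None:
        total = sum(s.weight for s in self.states)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state weights must sum to 1, got {total}")


#: Two-state parameters at the published arena/maze statistics: a fast-direct
#: state (90.8 +/- 28.3 mm/s, coherence 0.9 +/- 0.1, 68.1% of trials) and a
#: slow-assess state (32.5 +/- 13.9 mm/s, coherence 0.1 +/- 0.1).
PUBLISHED_STATE_PARAMS = StateTrajectoryParams(
    states=(
        MovementStateParams(90.8, 28.3, 0.9, 0.1, 0.681),
        MovementStateParams(32.5, 13.9, 0.1, 0.1, 0.319),
    )
)


def _simulate_headings(n: int, incoherence: float, rng: np.random.Generator) -> np.ndarray:
    """Heading angles: a slow sweep plus angular jitter.

    ``incoherence`` in [0, 1] maps 0 -> perfectly straight and 1 -> a full
    heading rotation over the window with angular jitter (meandering,
    assessment-like movement whose mean resultant length approaches zero).
    The sweep direction is random per trial.
    """
    omega = 2 * np.pi * incoherence / max(n - 1, 1) * (1 if rng.random() < 0.5 else -1)
    sigma = 0.08 * incoherence
    steps = omega + rng.normal(0.0, sigma, n)
    theta0 = rng.uniform(0, 2 * np.pi)
    return theta0 + np.concatenate([[0.0], np.cumsum(steps[1:])])


def _pipeline_R(theta: np.ndarray, smooth_window: int) -> float:
    """Mean resultant length of renormalized smoothed heading unit vectors."""
    import pandas as pd

    ux = np.cos(theta)
    uy = np.sin(theta)
    sx = pd.Series(ux).rolling(smooth_window, min_periods=1).mean().to_numpy()
    sy = pd.Series(uy).rolling(smooth_window, min_periods=1).mean().to_numpy()
    mag = np.hypot(sx, sy)
    keep = mag > 1e-12
    rx = sx[keep] / mag[keep]
    ry = sy[keep] / mag[keep]
    return float(np.hypot(rx.mean(), ry.mean()))


@lru_cache(maxsize=8)
def _coherence_curve(n_frames: int, smooth_window: int) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Monotone lookup: incoherence parameter -> expected pipeline coherence.

    Built once per (window length, smoothing) with a fixed internal RNG so
    the calibration is deterministic and independent of user seeds.
    """
    rng = np.random.default_rng(987654321)
    grid = np.linspace(0.0, 1.0, 21)
    means = []
    for c in grid:
        if c == 0.0:
            means.append(1.0)
            continue
        vals = [_pipeline_R(_simulate_headings(n_frames, c, rng)[1:], smooth_window)
                for _ in range(200)]
        means.append(float(np.mean(vals)))
    # enforce monotone decrease (Monte-Carlo jitter cleanup)
    m = np.minimum.accumulate(np.asarray(means))
    return tuple(grid), tuple(m)


def _incoherence_for_target(target_R: float, n_frames: int, smooth_window: int) -> float:
    grid, means = _coherence_curve(n_frames, smooth_window)
    g = np.asarray(grid)
    m = np.asarray(means)
    target = float(np.clip(target_R, m.min(), m.max()))
    # means decrease with incoherence; interpolate on the reversed axis
    return float(np.interp(target, m[::-1], g[::-1]))


def generate_state_trials(
    params: StateTrajectoryParams,
    n_trials: int,
    seed: int | np.random.Generator | None = None,
    frame_size: tuple[int, int] = (4096, 4096),
) -> tuple[list[PoseSeries], np.ndarray]:
    """Tail-base trajectories for stimulation trials (2 s pre + 2 s post).

    Trials are allocated to the two states in exact proportion to the
    mixture weights (order shuffled by the seed). Each trial has a constant
    speed drawn from its state's normal distribution and headings simulated
    so the analysis pipeline's coherence matches the state's target in
    expectation. Returns the trajectories and the ground-truth state labels
    (0 = first state, 1 = second).
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    rng = _require_seed(seed)
    n_frames = int(round(params.trial_duration_s * params.fps))
    n_pre = int(round(n_frames / 2))
    n0 = int(round(params.states[0].weight * n_trials))
    labels = np.array([0] * n0 + [1] * (n_trials - n0))
    rng.shuffle(labels)

    trials: list[PoseSeries] = []
    w, h = frame_size
    for lab in labels:
        state = params.states[lab]
        spd = max(1.0, rng.normal(state.speed_mean_mm_s, state.speed_sd_mm_s))
        target_R = float(np.clip(rng.normal(state.coherence_mean, state.coherence_sd),
                                 0.0, 1.0))
        c = _incoherence_for_target(target_R, n_pre, params.smooth_window)
        theta_pre = _simulate_headings(n_pre, c, rng)
        post_speed = spd
        post_c = c
        if params.post_effects is not None:
            mult, coh_override = params.post_effects[lab]
            post_speed = spd * mult
            if coh_override is not None:
                post_c = _incoherence_for_target(coh_override, n_frames - n_pre,
                                                 params.smooth_window)
        theta_post = _simulate_headings(n_frames - n_pre, post_c, rng)
        theta = np.concatenate([theta_pre, theta_post])
        step_px = np.concatenate([
            np.full(n_pre, spd), np.full(n_frames - n_pre, post_speed)
        ]) / params.scale_mm_per_px / params.fps
        dx = step_px * np.cos(theta)
        dy = step_px * np.sin(theta)
        x = w / 2.0 + np.concatenate([[0.0], np.cumsum(dx[1:])])
        y = h / 2.0 + np.concatenate([[0.0], np.cumsum(dy[1:])])
        x = np.clip(x, 0, w - 1)
        y = np.clip(y, 0, h - 1)
        trials.append(PoseSeries(
            bodyparts=("tail_base",),
            x=x[:, None], y=y[:, None],
            likelihood=np.full((n_frames, 1), 0.95),
            fps=params.fps, frame_size=frame_size,
        ))
    return trials, labels


# ---------------------------------------------------------------------------
# Response-latency trial generators
# ---------------------------------------------------------------------------


def _truncnorm_loc_for_mean(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter of a [lo, hi]-truncated normal with the given mean.

    A normal truncated to a window no longer has its location as its mean;
    the location is solved numerically so realized samples match the target
    mean in expectation.
    """

    def truncated_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))

    return float(optimize.brentq(lambda L: truncated_mean(L) - target_mean,
                                 lo - 8 * sd, hi + 8 * sd, xtol=1e-10))


def _sample_truncnorm(rng, mean, sd, lo, hi, size):
    loc = _truncnorm_loc_for_mean(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def generate_me_response_trials(
    n_trials: int,
    latency_mean_s: float = 4.74,
    latency_sd_s: float = 2.48,
    fps: float = 30.0,
    seed: int | np.random.Generator | None = None,
    window_s: float = 9.8,
    detect_lo_s: float = 1.6,
    detect_hi_s: float = 9.7,
    response_amp: float = 3000.0,
    artifact_amp: float = 50000.0,
    baseline_mean: float = 300.0,
    baseline_sd: float = 100.0,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Synthetic motion-energy traces with a prescribed latency distribution.

    Each trace spans +/- ~2x the analysis window around a nominal onset at
    the center sample; the true onset is jittered within +/-0.1 s and marked
    by a single-frame flash artifact; a sustained supra-threshold rise
    starts one latency after the true onset. Latencies are drawn from a
    normal truncated to the detection window with its location solved so the
    realized mean matches ``latency_mean_s``. Returns
    ``(traces, nominal_onset_index, true_latencies)``.
    """
    rng = _require_seed(seed)
    win = int(round(window_s * fps))
    pad = int(round(0.5 * fps))  # jitter + refinement margin
    length = 2 * (win + pad) + 1
    nominal = win + pad
    lats = _sample_truncnorm(rng, latency_mean_s, latency_sd_s, detect_lo_s, detect_hi_s,
                             n_trials)
    traces = np.clip(rng.normal(baseline_mean, baseline_sd, (n_trials, length)), 0.0, 900.0)
    jitter = rng.integers(-3, 4, n_trials)
    for i in range(n_trials):
        onset = nominal + int(jitter[i])
        traces[i, onset] += artifact_amp
        start = onset + int(round(lats[i] * fps))
        traces[i, start:] += response_amp
    return traces, nominal, lats


def generate_pose_response_trials(
    n_trials: int,
    latency_mean_s: float = 0.81,
    latency_sd_s: float = 1.65,
    fps: float = 30.0,
    seed: int | np.random.Generator | None = None,
    pre_s: float = 2.0,
    post_s: float = 10.0,
    step_px: float = 6.0,
    noise_sd_px: float = 0.3,
) -> tuple[list[dict], np.ndarray]:
    """Synthetic toe-keypoint trials: a baseline hold then a withdrawal step.

    Latencies are drawn from a normal truncated to the detectable window
    (one frame to just inside ``post_s``) with the location solved so the
    realized mean matches the target. Each trial dict carries ``x, y,
    likelihood, timestamps, stim_time``.
    """
    rng = _require_seed(seed)
    n = int(round((pre_s + post_s) * fps)) + 1
    t = np.arange(n) / fps - pre_s
    lats = _sample_truncnorm(rng, latency_mean_s, latency_sd_s, 1.5 / fps, post_s - 0.1,
                             n_trials)
    trials = []
    for i in range(n_trials):
        x = 500.0 + rng.normal(0.0, noise_sd_px, n)
        y = 500.0 + rng.normal(0.0, noise_sd_px, n)
        moved = t >= lats[i]
        x[moved] += step_px
        y[moved] += step_px
        trials.append({
            "x": x, "y": y,
            "likelihood": np.full(n, 0.95),
            "timestamps": t + pre_s,
            "stim_time": pre_s,
        })
    return trials, lats
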