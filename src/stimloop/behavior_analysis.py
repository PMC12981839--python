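"""Post-hoc analysis of keypoint trajectories and stimulation trials.

Pipelines implemented here:

* trajectory preprocessing (likelihood gating, tracking-jump removal, gap
  interpolation),
* locomotor speed with rolling-median smoothing and speed categories,
* stance/swing gait segmentation from paw displacement,
* motion-energy and pose-based response-latency extraction,
* heading coherence (mean resultant length of smoothed heading vectors),
* two-state Gaussian-mixture movement clustering and paired pre/post
  state-dependence statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .core_io import PoseSeries, FrameStack

__all__ = [
    "CleanTrajectory",
    "ResponseResult",
    "TrialState",
    "GaitResult",
    "ClusterResult",
    "SPEED_BIN_EDGES_PX_S",
    "SPEED_CATEGORIES",
    "preprocess",
    "speed",
    "categorize_speed",
    "gait_phases",
    "me_roi_trace",
    "me_latency",
    "pose_latency",
    "heading_coherence",
    "cluster_states",
    "state_dependence",
    "footprint_histogram",
]

#: Tail-base speed category edges in px/s; bins are lower-inclusive,
#: upper-exclusive: [0,20) stationary, [20,120) low, [120,220) medium,
#: [220, inf) high.
SPEED_BIN_EDGES_PX_S = (20.0, 120.0, 220.0)
SPEED_CATEGORIES = ("stationary", "low", "medium", "high")

#: Paw displacement below this (px/s) counts as a static frame in gait
#: segmentation — the same cutoff as the 'stationary' body-speed category.
STATIC_THRESHOLD_PX_S = 20.0


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


@dataclass
class CleanTrajectory:
    """A gap-filled single-keypoint trajectory.

    ``interpolated`` marks frames whose coordinates were filled in;
    ``missing`` marks boundary frames that could not be anchored on both
    sides and remain NaN.
    """

    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    interpolated: np.ndarray
    missing: np.ndarray
    fps: float
    scale_mm_per_px: float = 0.45
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.x), dtype=float) / self.fps

    @property
    def n_frames(self) -> int:
        return len(self.x)


def preprocess(
    series: PoseSeries,
    bodypart: str,
    likelihood_min: float = 0.8,
    jump_px: float = 30.0,
    scale_mm_per_px: float = 0.45,
) -> CleanTrajectory:
    """Clean one keypoint trajectory for analysis.

    Frames with likelihood not exceeding ``likelihood_min`` are dropped, as
    are frames whose Euclidean jump from the last retained frame exceeds
    ``jump_px`` (tracking glitches). Gaps are filled by linear interpolation
    between anchor values, each anchor being the mean of up to three valid
    frames on that side of the gap. Boundary gaps (no anchor on one side)
    are left missing, never extrapolated.
    """
    if series.n_frames == 0:
        raise ValueError("empty pose series")
    x, y, lik = series.part(bodypart)
    n = len(x)
    valid = lik > likelihood_min
    # remove jump glitches relative to the last valid frame
    last = None
    for i in range(n):
        if not valid[i]:
            continue
        if last is not None:
            if np.hypot(x[i] - x[last], y[i] - y[last]) > jump_px:
                valid[i] = False
                continue
        last = i

    cx = x.astype(float).copy()
    cy = y.astype(float).copy()
    interpolated = np.zeros(n, dtype=bool)
    missing = np.zeros(n, dtype=bool)
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        missing[:] = True
        cx[:] = np.nan
        cy[:] = np.nan
        return CleanTrajectory(cx, cy, lik.copy(), interpolated, missing, series.fps,
                               scale_mm_per_px, series.timestamps.copy())
    # boundary gaps
    cx[: idx[0]] = np.nan
    cy[: idx[0]] = np.nan
    missing[: idx[0]] = True
    cx[idx[-1] + 1 :] = np.nan
    cy[idx[-1] + 1 :] = np.nan
    missing[idx[-1] + 1 :] = True
    # interior gaps: linear interpolation between 3-frame anchor means
    for a, b in zip(idx, idx[1:]):
        if b - a == 1:
            continue
        left_anchor_x = x[idx[(idx <= a)][-3:]].mean()
        left_anchor_y = y[idx[(idx <= a)][-3:]].mean()
        right_anchor_x = x[idx[(idx >= b)][:3]].mean()
        right_anchor_y = y[idx[(idx >= b)][:3]].mean()
        gap = np.arange(a + 1, b)
        frac = (gap - a) / (b - a)
        cx[gap] = (1 - frac) * left_anchor_x + frac * right_anchor_x
        cy[gap] = (1 - frac) * left_anchor_y + frac * right_anchor_y
        interpolated[gap] = True
    return CleanTrajectory(cx, cy, lik.copy(), interpolated, missing, series.fps,
                           scale_mm_per_px, series.timestamps.copy())


# ---------------------------------------------------------------------------
# Speed
# ---------------------------------------------------------------------------


def speed(
    traj: CleanTrajectory, fps: float | None = None, median_window: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame speed traces ``(px_per_s, mm_per_s)``.

    Speed is the frame-to-frame Euclidean displacement divided by the frame
    time difference, smoothed with a rolling median of ``median_window``
    samples. The first frame repeats the first computable value so the trace
    aligns 1:1 with frames.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for a speed trace")
    ts = traj.timestamps
    dt = np.diff(ts)
    if np.any(dt <= 0):
        raise ValueError("non-increasing timestamps (zero delta-t)")
    dd = np.hypot(np.diff(traj.x), np.diff(traj.y))
    raw = np.concatenate([[np.nan], dd / dt])
    raw[0] = raw[1]
    smoothed = (
        pd.Series(raw).rolling(median_window, min_periods=1, center=True).median().to_numpy()
    )
    return smoothed, smoothed * traj.scale_mm_per_px


def categorize_speed(speed_px_s: np.ndarray) -> np.ndarray:
    """Category per frame from a px/s speed trace.

    Bins are lower-inclusive / upper-exclusive: [0, 20) stationary,
    [20, 120) low, [120, 220) medium, [220, inf) high.
    """
    v = np.asarray(speed_px_s, dtype=float)
    if np.any(v[~np.isnan(v)] < 0):
        raise ValueError("negative speeds are invalid")
    idx = np.digitize(v, SPEED_BIN_EDGES_PX_S, right=False)
    cats = np.array(SPEED_CATEGORIES, dtype=object)[idx]
    cats[np.isnan(v)] = None
    return cats


# ---------------------------------------------------------------------------
# Gait segmentation
# ---------------------------------------------------------------------------


@dataclass
class GaitResult:
    stance_durations_ms: np.ndarray
    swing_durations_ms: np.ndarray
    stance_mean_ms: float
    swing_mean_ms: float
    static_fraction_by_category: dict[str, float]
    static_labels: np.ndarray
    insufficient_data: bool = False


def gait_phases(
    paw_traj: CleanTrajectory,
    body_speed_px_s: np.ndarray | None = None,
    static_threshold_px_s: float = STATIC_THRESHOLD_PX_S,
) -> GaitResult:
    """Stance/swing segmentation of a paw trajectory.

    A frame is *static* when the paw's incoming displacement corresponds to a
    speed below ``static_threshold_px_s``; contiguous static runs are stance
    segments, moving runs are swing segments. Runs touching the series
    boundary are dropped from duration statistics (their true extent is
    unknown). Durations are run length times the frame interval, in ms.
    When a body-speed trace is supplied the fraction of static paw frames is
    reported per body-speed category.
    """
    fps = paw_traj.fps
    n = paw_traj.n_frames
    if n < 3:
        return GaitResult(np.array([]), np.array([]), np.nan, np.nan, {},
                          np.zeros(n, dtype=bool), insufficient_data=True)
    disp = np.hypot(np.diff(paw_traj.x), np.diff(paw_traj.y)) * fps
    static = np.empty(n, dtype=bool)
    static[1:] = disp < static_threshold_px_s
    static[0] = static[1]
    # NaN displacement (missing frames) counts as non-static nor swing; treat
    # as break by marking non-static (it will fall in a boundary-trimmed run
    # only if contiguous with the edges; interior NaNs are rare post-cleaning)
    nan_mask = np.concatenate([[False], np.isnan(disp)])
    static[nan_mask] = False

    # run-length encode
    change = np.flatnonzero(np.diff(static.astype(int))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    stance_ms = []
    swing_ms = []
    for k, (a, b) in enumerate(zip(starts, ends)):
        if a == 0 or b == n:  # boundary-truncated run
            continue
        dur = (b - a) * 1000.0 / fps
        (stance_ms if static[a] else swing_ms).append(dur)
    stance_arr = np.asarray(stance_ms)
    swing_arr = np.asarray(swing_ms)
    insufficient = stance_arr.size == 0 and swing_arr.size == 0

    frac_by_cat: dict[str, float] = {}
    if body_speed_px_s is not None:
        cats = categorize_speed(np.asarray(body_speed_px_s, dtype=float))
        for cat in SPEED_CATEGORIES:
            sel = cats == cat
            if np.any(sel):
                frac_by_cat[cat] = float(np.mean(static[sel]))
    return GaitResult(
        stance_durations_ms=stance_arr,
        swing_durations_ms=swing_arr,
        stance_mean_ms=float(stance_arr.mean()) if stance_arr.size else np.nan,
        swing_mean_ms=float(swing_arr.mean()) if swing_arr.size else np.nan,
        static_fraction_by_category=frac_by_cat,
        static_labels=static,
        insufficient_data=insufficient,
    )


# ---------------------------------------------------------------------------
# Motion-energy response latency
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseResult:
    responded: bool
    latency_s: float | None
    refined_onset_s: float | None
    exclusion: str = "none"  # none | not_idle | low_likelihood


def me_roi_trace(
    frames: FrameStack | np.ndarray,
    anchor_xy: tuple[float, float],
    radius_px: float = 15.0,
    suppress: float = 3.0,
) -> tuple[np.ndarray, bool]:
    """Motion energy inside a circular ROI anchored at a fixed keypoint.

    Per frame transition: absolute pixel difference, masked to the circular
    ROI, values below ``suppress`` zeroed, remainder summed. The anchor is
    the keypoint from the frame immediately before nominal stimulation onset
    and does not track the paw. Returns ``(trace, clipped)`` where
    ``clipped`` warns that the ROI extended past the frame edge.
    """
    arr = frames.frames if isinstance(frames, FrameStack) else np.asarray(frames)
    if arr.ndim != 3 or arr.shape[0] < 2:
        raise ValueError("need a (n>=2, h, w) frame stack")
    h, w = arr.shape[1:]
    cx, cy = anchor_xy
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
    clipped = bool(cx - radius_px < 0 or cy - radius_px < 0 or cx + radius_px > w - 1
                   or cy + radius_px > h - 1)
    diffs = np.abs(np.diff(arr.astype(np.int16), axis=0)).astype(float)
    diffs *= mask
    diffs[diffs < suppress] = 0.0
    return diffs.reshape(diffs.shape[0], -1).sum(axis=1), clipped


def me_latency(
    trace: np.ndarray,
    nominal_onset_index: int,
    fps: float = 30.0,
    threshold: float = 1000.0,
    refine_halfwidth_s: float = 0.2,
    window_s: float = 9.8,
    idle_until_s: float = 1.5,
) -> ResponseResult:
    """Response latency from a motion-energy trace around a stimulation.

    The nominal onset is refined to the largest peak (the single-frame
    stimulus flash artifact) within +/-0.2 s; the trace is re-windowed to
    +/-9.8 s around the refined onset with the artifact sample zeroed,
    denoised with a 3-sample median then a 7-sample Gaussian (sigma = 2),
    and thresholded. Any crossing in (0, 1.5) s marks the trial not idle
    (excluded); otherwise the trial responds if the first crossing at or
    above ``threshold`` falls in [1.5, 9.8] s, and the latency is that
    crossing time relative to the refined onset.
    """
    trace = np.asarray(trace, dtype=float)
    half = int(round(refine_halfwidth_s * fps))
    win = int(round(window_s * fps))
    lo = max(0, nominal_onset_index - half)
    hi = min(len(trace), nominal_onset_index + half + 1)
    if hi <= lo:
        raise ValueError("nominal onset outside trace")
    refined = lo + int(np.argmax(trace[lo:hi]))
    if refined - win < 0 or refined + win >= len(trace):
        raise ValueError(
            f"trace too short: need +/-{window_s} s around the refined onset"
        )
    seg = trace[refined - win : refined + win + 1].copy()
    onset_i = win
    seg[onset_i] = 0.0  # single-frame flash artifact at t = 0
    seg = signal.medfilt(seg, kernel_size=3)
    seg = ndimage.gaussian_filter1d(seg, sigma=2, radius=3)
    t = (np.arange(len(seg)) - onset_i) / fps
    crossing = seg >= threshold
    early = crossing & (t > 0) & (t < idle_until_s)
    if np.any(early):
        return ResponseResult(False, None, refined / fps, exclusion="not_idle")
    in_window = crossing & (t >= idle_until_s) & (t <= window_s)
    if not np.any(in_window):
        return ResponseResult(False, None, refined / fps)
    latency = float(t[np.flatnonzero(in_window)[0]])
    return ResponseResult(True, latency, refined / fps)


def pose_latency(
    x: np.ndarray,
    y: np.ndarray,
    likelihood: np.ndarray,
    timestamps: np.ndarray,
    stim_time_s: float,
    threshold_px: float = 3.0,
    likelihood_min: float = 0.8,
    baseline_s: float = 2.0,
    window_s: float = 10.0,
) -> ResponseResult:
    """Response latency from a toe-keypoint trajectory.

    The baseline is the mean coordinate over [-2, 0) s before the stimulus
    (likelihood-gated). The trial responds if the Euclidean distance from
    baseline strictly exceeds ``threshold_px`` at any likelihood-gated frame
    in (0, 10] s; latency is the first such time after onset.
    """
    t = np.asarray(timestamps, dtype=float) - stim_time_s
    ok = np.asarray(likelihood, dtype=float) > likelihood_min
    base = (t >= -baseline_s) & (t < 0) & ok
    if not np.any(base):
        return ResponseResult(False, None, None, exclusion="low_likelihood")
    bx = np.mean(np.asarray(x, dtype=float)[base])
    by = np.mean(np.asarray(y, dtype=float)[base])
    post = (t > 0) & (t <= window_s) & ok
    dist = np.hypot(np.asarray(x, dtype=float) - bx, np.asarray(y, dtype=float) - by)
    moved = post & (dist > threshold_px)
    if not np.any(moved):
        return ResponseResult(False, None, 0.0)
    return ResponseResult(True, float(t[np.flatnonzero(moved)[0]]), 0.0)


# ---------------------------------------------------------------------------
# Heading coherence
# ---------------------------------------------------------------------------


def heading_coherence(
    x: np.ndarray,
    y: np.ndarray,
    smooth_window: int = 10,
    eval_frames: int | None = None,
) -> float:
    """Mean resultant length R of smoothed per-frame heading vectors.

    Headings come from consecutive displacements; zero-displacement frames
    carry the last defined heading forward (frames before the first defined
    heading are dropped). Unit heading vectors are averaged over a trailing
    ``smooth_window`` (partial windows at the start) and renormalized; R is
    the norm of the mean of those unit vectors over the last ``eval_frames``
    (all frames when ``None``). R = 1 for a straight path, ~0 for
    directionally incoherent movement.
    """
    dx = np.diff(np.asarray(x, dtype=float))
    dy = np.diff(np.asarray(y, dtype=float))
    norm = np.hypot(dx, dy)
    defined = norm > 0
    if not np.any(defined):
        raise ValueError("no displacement: headings undefined everywhere")
    ux = np.where(defined, dx / np.where(norm == 0, 1, norm), np.nan)
    uy = np.where(defined, dy / np.where(norm == 0, 1, norm), np.nan)
    # carry the last defined heading forward
    first = int(np.flatnonzero(defined)[0])
    for i in range(first + 1, len(ux)):
        if not defined[i]:
            ux[i] = ux[i - 1]
            uy[i] = uy[i - 1]
    ux = ux[first:]
    uy = uy[first:]
    sx = pd.Series(ux).rolling(smooth_window, min_periods=1).mean().to_numpy()
    sy = pd.Series(uy).rolling(smooth_window, min_periods=1).mean().to_numpy()
    mag = np.hypot(sx, sy)
    # renormalize; a fully cancelled window keeps the previous direction
    with np.errstate(invalid="ignore"):
        rx = np.where(mag > 1e-12, sx / np.where(mag == 0, 1, mag), np.nan)
        ry = np.where(mag > 1e-12, sy / np.where(mag == 0, 1, mag), np.nan)
    for i in range(1, len(rx)):
        if np.isnan(rx[i]):
            rx[i] = rx[i - 1]
            ry[i] = ry[i - 1]
    keep = ~np.isnan(rx)
    rx, ry = rx[keep], ry[keep]
    if eval_frames is not None:
        rx, ry = rx[-eval_frames:], ry[-eval_frames:]
    if rx.size == 0:
        raise ValueError("no defined headings in the evaluation window")
    return float(np.hypot(rx.mean(), ry.mean()))


# ---------------------------------------------------------------------------
# Movement-state clustering and state dependence
# ---------------------------------------------------------------------------


@dataclass
class TrialState:
    """Pre/post stimulus movement descriptors for one trial."""

    pre_speed_mm_s: float
    pre_coherence: float
    post_speed_mm_s: float
    post_coherence: float
    label: str | None = None

    @property
    def delta_speed(self) -> float:
        return self.post_speed_mm_s - self.pre_speed_mm_s

    @property
    def delta_coherence(self) -> float:
        return self.post_coherence - self.pre_coherence


@dataclass
class ClusterResult:
    labels: np.ndarray  # semantic: "fast-direct" | "slow-assess"
    proportions: dict[str, float]
    speed_mean: dict[str, float]
    speed_sd: dict[str, float]
    coherence_mean: dict[str, float]
    coherence_sd: dict[str, float]
    degenerate_warning: bool


FAST = "fast-direct"
SLOW = "slow-assess"


def cluster_states(
    speeds_mm_s: np.ndarray,
    coherences: np.ndarray,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterResult:
    """Two-component Gaussian-mixture clustering of (speed, coherence).

    Features are standardized internally; the component with the higher mean
    speed (original units) is labeled ``fast-direct``, the other
    ``slow-assess`` — semantic labels never depend on component index.
    A silhouette score below zero flags a degenerate clustering.
    """
    v = np.asarray(speeds_mm_s, dtype=float)
    r = np.asarray(coherences, dtype=float)
    if v.shape != r.shape or v.ndim != 1:
        raise ValueError("speeds and coherences must be 1-D arrays of equal length")
    if v.size < 10:
        raise ValueError("need at least 10 trials for mixture clustering")
    X = np.column_stack([v, r])
    Z = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-12)
    gmm = GaussianMixture(
        n_components=2, covariance_type="full", n_init=n_init, random_state=seed
    ).fit(Z)
    comp = gmm.predict(Z)
    mean_speed = [v[comp == k].mean() if np.any(comp == k) else -np.inf for k in (0, 1)]
    fast_comp = int(np.argmax(mean_speed))
    labels = np.where(comp == fast_comp, FAST, SLOW)
    degenerate = len(set(comp)) < 2
    if not degenerate:
        degenerate = silhouette_score(Z, comp) < 0
    out = ClusterResult(
        labels=labels,
        proportions={},
        speed_mean={},
        speed_sd={},
        coherence_mean={},
        coherence_sd={},
        degenerate_warning=bool(degenerate),
    )
    for lab in (FAST, SLOW):
        sel = labels == lab
        out.proportions[lab] = float(np.mean(sel))
        out.speed_mean[lab] = float(v[sel].mean()) if np.any(sel) else np.nan
        out.speed_sd[lab] = float(v[sel].std(ddof=1)) if sel.sum() > 1 else np.nan
        out.coherence_mean[lab] = float(r[sel].mean()) if np.any(sel) else np.nan
        out.coherence_sd[lab] = float(r[sel].std(ddof=1)) if sel.sum() > 1 else np.nan
    return out


def state_dependence(trials: Sequence[TrialState], labels: np.ndarray | None = None) -> pd.DataFrame:
    """Per-cluster paired post-pre deltas with t statistics.

    For each cluster and each feature (speed, coherence) the within-trial
    delta (post - pre) is tested against zero change (one-sample t, the
    Welch form for a single sample) and between clusters with Welch's
    unequal-variance two-sample t. Degenerate zero-variance deltas are
    reported as undefined with a flag. Returns a tidy DataFrame.
    """
    trials = list(trials)
    if labels is None:
        labels = np.array([t.label for t in trials], dtype=object)
    labels = np.asarray(labels, dtype=object)
    rows = []
    deltas = {
        "speed": np.array([t.delta_speed for t in trials]),
        "coherence": np.array([t.delta_coherence for t in trials]),
    }
    for lab in (FAST, SLOW):
        sel = labels == lab
        for feat, d in deltas.items():
            dsel = d[sel]
            if dsel.size < 2:
                continue
            if np.std(dsel, ddof=1) == 0:
                if dsel.mean() == 0:  # no change anywhere: no effect, not degenerate
                    rows.append({"cluster": lab, "feature": feat, "n": int(dsel.size),
                                 "mean_delta": 0.0, "t": 0.0, "p": 1.0,
                                 "degenerate": False})
                else:  # constant nonzero shift: t undefined (zero variance)
                    rows.append({"cluster": lab, "feature": feat, "n": int(dsel.size),
                                 "mean_delta": float(dsel.mean()), "t": np.nan,
                                 "p": np.nan, "degenerate": True})
                continue
            t_stat, p = stats.ttest_1samp(dsel, 0.0)
            rows.append({"cluster": lab, "feature": feat, "n": int(dsel.size),
                         "mean_delta": float(dsel.mean()), "t": float(t_stat),
                         "p": float(p), "degenerate": False})
    for feat, d in deltas.items():
        a = d[labels == FAST]
        b = d[labels == SLOW]
        if a.size >= 2 and b.size >= 2 and (np.std(a, ddof=1) > 0 or np.std(b, ddof=1) > 0):
            t_stat, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append({"cluster": "between", "feature": feat, "n": int(a.size + b.size),
                         "mean_delta": float(a.mean() - b.mean()), "t": float(t_stat),
                         "p": float(p), "degenerate": False})
    return pd.DataFrame(rows)


def footprint_histogram(
    x: np.ndarray, y: np.ndarray, bins: int | Sequence[int] = 50,
    range_: Sequence[Sequence[float]] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D dwell histogram of a paw keypoint (stance phases show as maxima)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    return np.histogram2d(x[keep], y[keep], bins=bins, range=range_)


def count_dwell_maxima(hist: np.ndarray, min_count: float = 1.0) -> int:
    """Number of local maxima in a dwell histogram (8-connected, plateau-safe)."""
    footprint = np.ones((3, 3), dtype=bool)
    local_max = (hist == ndimage.maximum_filter(hist, footprint=footprint)) & (hist >= min_count)
    labeled, n = ndimage.label(local_max)
    return int(n)
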