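"""Random-access multi-animal stimulation across chamber grids.

Each chamber of a grid (default 3x3 of 230x230 px crops) is monitored by
motion energy — the summed, noise-suppressed absolute frame-to-frame pixel
difference inside its ROI. A mouse is idle when every transition in the
trailing 2 s window stays below the idle threshold; idle mice outside their
scheduler refractory are selected pseudo-randomly for cropping, pose
estimation and stimulation. Keypoints estimated on a crop are translated
back to full-frame pixels before targeting.

The 30,000-unit idle threshold is calibrated for 8-bit frames and a
230x230 px ROI; other bit depths or crop sizes need re-tuning, so all
thresholds live in configuration.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import FrameStack
from .virtual_rig import _require_seed

__all__ = [
    "ChamberGrid",
    "default_grid",
    "motion_energy",
    "detect_idle",
    "schedule",
    "crop",
    "to_fullframe",
    "run_chamber_session",
]


@dataclass
class ChamberGrid:
    """Chamber ROIs in full-frame pixels plus per-chamber scheduling state."""

    rows: int
    cols: int
    rois: list[tuple[int, int, int, int]]  # (x0, y0, width, height)
    last_stimulus_s: np.ndarray = field(default=None)  # type: ignore[assignment]
    frame_size: tuple[int, int] = (1100, 1100)

    def __post_init__(self) -> None:
        if self.rows * self.cols < 1 or len(self.rois) != self.rows * self.cols:
            raise ValueError("ROI count must equal rows*cols >= 1")
        w, h = self.frame_size
        for x0, y0, rw, rh in self.rois:
            if x0 < 0 or y0 < 0 or x0 + rw > w or y0 + rh > h:
                raise ValueError("chamber ROI extends outside the frame")
        for a in range(len(self.rois)):
            for b in range(a + 1, len(self.rois)):
                ax, ay, aw, ah = self.rois[a]
                bx, by, bw, bh = self.rois[b]
                if ax < bx + bw and bx < ax + aw and ay < by + bh and by < ay + ah:
                    raise ValueError(f"chambers {a} and {b} overlap")
        if self.last_stimulus_s is None:
            self.last_stimulus_s = np.full(len(self.rois), -np.inf)

    @property
    def n_chambers(self) -> int:
        return len(self.rois)


def default_grid(rows: int = 3, cols: int = 3, crop_px: int = 230,
                 frame_size: tuple[int, int] | None = None) -> ChamberGrid:
    """Non-overlapping rows x cols grid of square crops tiled from the origin."""
    if frame_size is None:
        frame_size = (cols * crop_px, rows * crop_px)
    rois = [(c * crop_px, r * crop_px, crop_px, crop_px)
            for r in range(rows) for c in range(cols)]
    return ChamberGrid(rows=rows, cols=cols, rois=rois, frame_size=frame_size)


def motion_energy(
    frames: FrameStack | np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    noise_floor: float = 10.0,
) -> np.ndarray:
    """Per-transition motion energy inside an ROI.

    Absolute frame-to-frame pixel differences within the ROI; values below
    ``noise_floor`` are zeroed before summing. Trace length is one less than
    the frame count.
    """
    arr = frames.frames if isinstance(frames, FrameStack) else np.asarray(frames)
    if arr.ndim != 3 or arr.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    h, w = arr.shape[1:]
    if roi is not None:
        x0, y0, rw, rh = roi
        if x0 < 0 or y0 < 0 or x0 + rw > w or y0 + rh > h:
            raise ValueError(f"ROI {roi} outside frame {(w, h)}")
        arr = arr[:, y0 : y0 + rh, x0 : x0 + rw]
    diffs = np.abs(np.diff(arr.astype(np.int32), axis=0)).astype(float)
    diffs[diffs < noise_floor] = 0.0
    return diffs.reshape(diffs.shape[0], -1).sum(axis=1)


def detect_idle(
    trace: np.ndarray,
    threshold: float = 30000.0,
    window_s: float = 2.0,
    fps: float = 30.0,
) -> np.ndarray:
    """Per-frame idle flags from a motion-energy trace.

    Frame ``f`` is idle iff every transition in the trailing ``window_s``
    window is strictly below the threshold. Returns a boolean array aligned
    to frames (length ``len(trace) + 1``); frames before the first full
    window are False (warm-up).
    """
    trace = np.asarray(trace, dtype=float)
    w = int(round(window_s * fps))
    if len(trace) < w:
        raise ValueError(f"trace shorter than the {window_s} s window ({w} transitions)")
    quiet = trace < threshold
    idle = np.zeros(len(trace) + 1, dtype=bool)
    run = np.cumsum(np.concatenate([[0], quiet.astype(int)]))
    for f in range(w, len(trace) + 1):
        idle[f] = (run[f] - run[f - w]) == w
    return idle


def schedule(
    grid: ChamberGrid,
    idle_flags: Sequence[bool],
    now_s: float,
    refractory_s: float = 10.0,
    seed: int | np.random.Generator | None = None,
) -> int | None:
    """Pseudo-randomly pick an idle chamber outside its refractory.

    Uniform choice over eligible chambers from the seeded stream; ``None``
    when no chamber is eligible.
    """
    rng = _require_seed(seed)
    eligible = [i for i in range(grid.n_chambers)
                if idle_flags[i] and now_s - grid.last_stimulus_s[i] > refractory_s]
    if not eligible:
        return None
    return int(eligible[rng.integers(len(eligible))])


def crop(frame: np.ndarray, grid: ChamberGrid, chamber: int) -> np.ndarray:
    """Exact ROI extraction of one chamber from a full frame."""
    if not (0 <= chamber < grid.n_chambers):
        raise ValueError(f"invalid chamber id {chamber}")
    x0, y0, w, h = grid.rois[chamber]
    return np.asarray(frame)[y0 : y0 + h, x0 : x0 + w]


def to_fullframe(grid: ChamberGrid, chamber: int, xy: tuple[float, float]) -> tuple[float, float]:
    """Translate crop-local keypoint coordinates back to full-frame pixels."""
    if not (0 <= chamber < grid.n_chambers):
        raise ValueError(f"invalid chamber id {chamber}")
    x0, y0, _, _ = grid.rois[chamber]
    return (xy[0] + x0, xy[1] + y0)


def run_chamber_session(
    traces: np.ndarray,
    fps: float = 30.0,
    threshold: float = 30000.0,
    window_s: float = 2.0,
    scheduler_refractory_s: float = 10.0,
    per_mouse_isi_s: float = 60.0,
    seed: int | np.random.Generator | None = None,
    grid: ChamberGrid | None = None,
) -> list[tuple[float, int]]:
    """Drive the full multi-chamber loop over per-chamber motion traces.

    ``traces`` is ``(n_chambers, n_transitions)``. At each frame the idle
    flags are evaluated, one eligible chamber (idle, outside both the
    scheduler refractory and the per-mouse inter-stimulus spacing) is
    selected, and a stimulation is recorded at that frame time. Returns
    ``(time_s, chamber)`` pairs.
    """
    traces = np.asarray(traces, dtype=float)
    n_chambers, n_trans = traces.shape
    if grid is None:
        grid = default_grid(1, n_chambers)
    rng = _require_seed(seed)
    idle = np.stack([detect_idle(traces[c], threshold, window_s, fps)
                     for c in range(n_chambers)])
    spacing = max(scheduler_refractory_s, per_mouse_isi_s)
    out: list[tuple[float, int]] = []
    for f in range(n_trans + 1):
        t = f / fps
        flags = [idle[c, f] and t - grid.last_stimulus_s[c] > spacing
                 for c in range(n_chambers)]
        choice = schedule(grid, flags, t, refractory_s=scheduler_refractory_s, seed=rng)
        if choice is not None:
            grid.last_stimulus_s[choice] = t
            out.append((t, choice))
    return out
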