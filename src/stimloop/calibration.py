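"""Pixel-to-voltage calibration of the laser-steering galvanometers.

The steerable laser is characterized by raster-stepping the mirrors over a
grid of commanded voltage pairs, imaging the laser spot at each step, and
fitting two-dimensional polynomial surfaces ``Vx(x, y)`` and ``Vy(x, y)``
that return the mirror voltages steering the beam to any camera pixel. The
fit direction (voltage as a function of pixel) is chosen so lookups during
closed-loop control are a single polynomial evaluation.

Also provided: sub-pixel laser-spot detection, held-out evaluation of a
fitted map, drift QC against a re-map threshold, and the geometric and
uniformity summaries used to characterize the optical path (chessboard scale
factor, focal-length variability over the platform, coefficient of
variation of power measurements).
"""
from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "RasterObservation",
    "CalibrationMap",
    "CalibrationError",
    "CalibrationFitError",
    "CalibrationDomainError",
    "SpotDetectionError",
    "make_raster",
    "detect_spot",
    "fit_map",
    "predict_voltage",
    "evaluate_map",
    "EvaluationResult",
    "chessboard_scale",
    "ChessboardResult",
    "focal_length_variability",
    "uniformity_stats",
]


class CalibrationError(ValueError):
    pass


class CalibrationFitError(CalibrationError):
    """Rank-deficient or otherwise infeasible surface fit."""


class CalibrationDomainError(CalibrationError):
    """Pixel query outside the calibrated domain (and clamping disabled)."""


class SpotDetectionError(CalibrationError):
    """No laser spot above the background floor."""


@dataclass(frozen=True)
class RasterObservation:
    """One raster step: commanded voltages and the observed spot pixel."""

    voltages: tuple[float, float]
    pixel: tuple[float, float]
    peak_intensity: float = 255.0


# ---------------------------------------------------------------------------
# Raster acquisition and spot detection
# ---------------------------------------------------------------------------


def make_raster(
    nx: int = 100,
    ny: int = 100,
    voltage_bounds: tuple[tuple[float, float], tuple[float, float]] = ((-5.0, 5.0), (-5.0, 5.0)),
) -> np.ndarray:
    """Regular ``nx * ny`` grid of commanded voltage pairs covering the bounds.

    Returns an ``(nx * ny, 2)`` array, x fastest. The default 100 x 100 grid
    yields 10,000 raster points.
    """
    if nx < 2 or ny < 2:
        raise CalibrationError("raster requires nx, ny >= 2")
    (x0, x1), (y0, y1) = voltage_bounds
    if not (x1 > x0 and y1 > y0):
        raise CalibrationError("degenerate voltage bounds")
    vx = np.linspace(x0, x1, nx)
    vy = np.linspace(y0, y1, ny)
    gx, gy = np.meshgrid(vx, vy)
    return np.column_stack([gx.ravel(), gy.ravel()])


def detect_spot(frame: np.ndarray, background_floor: float = 0.0) -> tuple[float, float]:
    """Sub-pixel laser-spot location in a grayscale frame.

    The spot is the intensity-weighted centroid of the connected region
    around the global maximum. When several connected components contain a
    global-maximum pixel, the one with the largest summed intensity wins;
    an exact tie is broken toward the component whose peak has the smaller
    ``(y, x)``. Returns ``(x, y)``.
    """
    frame = np.asarray(frame, dtype=float)
    peak = frame.max()
    if peak <= background_floor:
        raise SpotDetectionError(
            f"no pixel above background floor {background_floor} (max {peak})"
        )
    mask = frame > background_floor
    labels, _ = ndimage.label(mask)
    peak_positions = np.argwhere(frame == peak)
    candidates = sorted(
        {int(labels[tuple(pos)]) for pos in peak_positions}
    )
    best_label = None
    best_key = None
    for lab in candidates:
        total = frame[labels == lab].sum()
        lab_peaks = [tuple(p) for p in peak_positions if labels[tuple(p)] == lab]
        key = (-total, min(lab_peaks))
        if best_key is None or key < best_key:
            best_key = key
            best_label = lab
    comp = labels == best_label
    ys, xs = np.nonzero(comp)
    w = frame[ys, xs]
    return (float(np.sum(xs * w) / np.sum(w)), float(np.sum(ys * w) / np.sum(w)))


# ---------------------------------------------------------------------------
# Surface fit
# ---------------------------------------------------------------------------


def _monomial_exponents(degree: int) -> list[tuple[int, int]]:
    return [(i, j) for total in range(degree + 1) for i in range(total + 1) for j in [total - i]]


def _design_matrix(px: np.ndarray, exponents: Sequence[tuple[int, int]],
                   center: np.ndarray, scale: np.ndarray) -> np.ndarray:
    u = (px - center) / scale
    return np.column_stack([u[:, 0] ** i * u[:, 1] ** j for i, j in exponents])


@dataclass
class CalibrationMap:
    """Fitted polynomial surfaces mapping pixel coordinates to voltages."""

    degree: int
    coeff_vx: np.ndarray
    coeff_vy: np.ndarray
    center: np.ndarray  # pixel-normalization center
    scale: np.ndarray  # pixel-normalization half-width
    domain: tuple[tuple[float, float], tuple[float, float]]  # ((xmin,xmax),(ymin,ymax))
    residual_mae_px: float
    residual_mae_volts: float
    created: float = field(default_factory=_time.time)

    @property
    def exponents(self) -> list[tuple[int, int]]:
        return _monomial_exponents(self.degree)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "degree": self.degree,
            "coeff_vx": list(map(float, self.coeff_vx)),
            "coeff_vy": list(map(float, self.coeff_vy)),
            "center": list(map(float, self.center)),
            "scale": list(map(float, self.scale)),
            "domain": [list(self.domain[0]), list(self.domain[1])],
            "residual_mae_px": self.residual_mae_px,
            "residual_mae_volts": self.residual_mae_volts,
            "created": self.created,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationMap":
        d = json.loads(Path(path).read_text())
        return cls(
            degree=d["degree"],
            coeff_vx=np.asarray(d["coeff_vx"]),
            coeff_vy=np.asarray(d["coeff_vy"]),
            center=np.asarray(d["center"]),
            scale=np.asarray(d["scale"]),
            domain=(tuple(d["domain"][0]), tuple(d["domain"][1])),
            residual_mae_px=d["residual_mae_px"],
            residual_mae_volts=d["residual_mae_volts"],
            created=d["created"],
        )


def _as_arrays(observations: Sequence[RasterObservation]) -> tuple[np.ndarray, np.ndarray]:
    px = np.array([o.pixel for o in observations], dtype=float)
    volts = np.array([o.voltages for o in observations], dtype=float)
    return px, volts


def fit_map(observations: Sequence[RasterObservation], degree: int = 3) -> CalibrationMap:
    """Least-squares polynomial surfaces ``V(x, y)`` per voltage axis.

    Pixels are normalized to the observation bounding box for conditioning.
    The stored residual MAE is the mean Euclidean voltage residual converted
    to pixels through the linear pixel-per-volt gain estimated from the same
    observations. Raises :class:`CalibrationFitError` on rank deficiency
    (e.g. collinear observations or too few points for the degree).
    """
    if degree < 1:
        raise CalibrationError("degree must be >= 1")
    observations = list(observations)
    exponents = _monomial_exponents(degree)
    n_coef = len(exponents)
    if len(observations) < n_coef:
        raise CalibrationFitError(
            f"need at least {n_coef} observations for degree {degree}, got {len(observations)}"
        )
    px, volts = _as_arrays(observations)
    lo = px.min(axis=0)
    hi = px.max(axis=0)
    center = (lo + hi) / 2
    scale = np.maximum((hi - lo) / 2, 1e-12)
    A = _design_matrix(px, exponents, center, scale)
    rank = np.linalg.matrix_rank(A)
    if rank < n_coef:
        raise CalibrationFitError(
            f"rank-deficient design matrix (rank {rank} < {n_coef} coefficients); "
            "observations may be collinear"
        )
    coef, *_ = np.linalg.lstsq(A, volts, rcond=None)
    resid_v = volts - A @ coef
    mae_volts = float(np.mean(np.linalg.norm(resid_v, axis=1)))

    # linear volts -> pixel gain for expressing the residual in pixels
    V1 = np.column_stack([np.ones(len(volts)), volts])
    lin, *_ = np.linalg.lstsq(V1, px, rcond=None)
    J = lin[1:, :].T  # d(pixel)/d(voltage), 2x2
    mae_px = float(np.mean(np.linalg.norm(resid_v @ J.T, axis=1)))

    return CalibrationMap(
        degree=degree,
        coeff_vx=coef[:, 0],
        coeff_vy=coef[:, 1],
        center=center,
        scale=scale,
        domain=((float(lo[0]), float(hi[0])), (float(lo[1]), float(hi[1]))),
        residual_mae_px=mae_px,
        residual_mae_volts=mae_volts,
    )


def predict_voltage(
    cmap: CalibrationMap, pixel: np.ndarray | Sequence[float], clamp: bool = False
) -> np.ndarray:
    """Voltage pair(s) steering the laser to the given pixel(s).

    ``pixel`` may be one ``(x, y)`` pair or an ``(n, 2)`` array. Queries
    outside the calibrated domain raise :class:`CalibrationDomainError`
    unless ``clamp=True``, which projects them onto the domain boundary.
    """
    p = np.atleast_2d(np.asarray(pixel, dtype=float))
    (x0, x1), (y0, y1) = cmap.domain
    lo = np.array([x0, y0])
    hi = np.array([x1, y1])
    if clamp:
        p = np.clip(p, lo, hi)
    else:
        eps = 1e-9
        if np.any(p < lo - eps) or np.any(p > hi + eps):
            raise CalibrationDomainError(
                f"pixel outside calibrated domain {cmap.domain}; pass clamp=True to project"
            )
    A = _design_matrix(p, cmap.exponents, cmap.center, cmap.scale)
    volts = np.column_stack([A @ cmap.coeff_vx, A @ cmap.coeff_vy])
    return volts[0] if np.asarray(pixel).ndim == 1 else volts


@dataclass(frozen=True)
class EvaluationResult:
    mae_px: float
    mae_mm: float | None
    n: int
    needs_remap: bool


def evaluate_map(
    cmap: CalibrationMap,
    heldout: Sequence[RasterObservation] | np.ndarray,
    forward: Callable[[np.ndarray], np.ndarray],
    scale_mm_per_px: float | None = None,
    remap_threshold_mm: float = 1.94,
) -> EvaluationResult:
    """Held-out mean Euclidean error of a calibration map, in pixels (and mm).

    For each held-out target pixel the map predicts voltages, ``forward``
    realizes the laser spot those voltages produce (the rig ground truth),
    and the error is the distance between realized spot and target.
    ``needs_remap`` flags drift beyond ``remap_threshold_mm`` (the weekly
    platform-drift level at which a fresh raster map is recommended);
    it stays ``None``-safe by flagging only when a scale factor is known.
    """
    if isinstance(heldout, np.ndarray):
        targets = np.atleast_2d(heldout)
    else:
        heldout = list(heldout)
        if len(heldout) == 0:
            raise CalibrationError("held-out observation set is empty")
        targets = np.array([o.pixel for o in heldout], dtype=float)
    if targets.size == 0:
        raise CalibrationError("held-out observation set is empty")
    volts = predict_voltage(cmap, targets)
    spots = np.atleast_2d(np.asarray(forward(volts), dtype=float))
    err = np.linalg.norm(spots - targets, axis=1)
    mae_px = float(np.mean(err))
    mae_mm = mae_px * scale_mm_per_px if scale_mm_per_px is not None else None
    needs_remap = bool(mae_mm is not None and mae_mm > remap_threshold_mm)
    return EvaluationResult(mae_px=mae_px, mae_mm=mae_mm, n=len(err), needs_remap=needs_remap)


# ---------------------------------------------------------------------------
# Geometric / uniformity summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChessboardResult:
    scale_mm_per_px: float
    spacing_range_px: float
    mean_spacing_px: float
    qc_warning: bool


def chessboard_scale(corner_grid: np.ndarray, square_size_mm: float) -> ChessboardResult:
    """Scale factor (mm/pixel) from detected chessboard corner positions.

    ``corner_grid`` is ``(rows, cols, 2)`` pixel coordinates of the inner
    corners of a chessboard of ``square_size_mm`` squares. The scale is the
    square size divided by the mean Euclidean inter-corner spacing pooled
    over rows and columns; the min-max spacing range is reported as a
    flatness QC, and a spacing coefficient of variation above 10% sets
    ``qc_warning``.
    """
    corners = np.asarray(corner_grid, dtype=float)
    if corners.ndim != 3 or corners.shape[2] != 2 or corners.shape[0] < 2 or corners.shape[1] < 2:
        raise CalibrationError("corner grid must be (rows >= 2, cols >= 2, 2)")
    if square_size_mm <= 0:
        raise CalibrationError("square size must be positive")
    along_rows = np.linalg.norm(np.diff(corners, axis=1), axis=2).ravel()
    along_cols = np.linalg.norm(np.diff(corners, axis=0), axis=2).ravel()
    spacings = np.concatenate([along_rows, along_cols])
    mean_spacing = float(spacings.mean())
    cv = float(spacings.std() / mean_spacing)
    return ChessboardResult(
        scale_mm_per_px=square_size_mm / mean_spacing,
        spacing_range_px=float(spacings.max() - spacings.min()),
        mean_spacing_px=mean_spacing,
        qc_warning=cv > 0.10,
    )


def focal_length_variability(height_m: float, region_radius_m: float) -> float:
    """Maximum beam-path-length variability (%) over a planar circular region.

    The beam travels ``sqrt(height^2 + r^2)`` to a point at radial offset
    ``r``; the variability is ``(max - min) / min`` over the region, as a
    percentage. The minimum is directly beneath the galvanometers.
    """
    if height_m <= 0:
        raise CalibrationError("height must be positive")
    if region_radius_m < 0:
        raise CalibrationError("region radius must be non-negative")
    longest = float(np.hypot(height_m, region_radius_m))
    return (longest - height_m) / height_m * 100.0


def uniformity_stats(measurements: Sequence[float] | np.ndarray) -> float:
    """Coefficient of variation (population sd / mean) of grid measurements."""
    values = np.asarray(measurements, dtype=float)
    if values.size < 2:
        raise CalibrationError("need at least 2 measurements")
    mean = values.mean()
    if mean == 0:
        raise CalibrationError("coefficient of variation undefined for zero mean")
    return float(values.std(ddof=0) / mean)
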