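"""Shared domain types and file I/O.

Conventions used throughout the package:

* Pixel coordinates are 0-based with the origin at the top-left of the
  camera frame, x increasing rightward and y increasing downward (the image
  raster convention). Physical units (mm) are obtained only through a
  configured scale factor (mm per pixel).
* Timestamps are seconds as floating point; when synthesized from frame
  indices the frame interval is exactly ``1 / fps``.
* Missing keypoint estimates are represented by likelihood 0 and are never
  interpolated at read time; gap filling is the job of
  :mod:`stimloop.behavior_analysis`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EVENT_KINDS",
    "DEFAULT_BODYPARTS",
    "PoseSeries",
    "FrameStack",
    "EventRecord",
    "Config",
    "PoseFormatError",
    "PoseParseError",
    "EventLogError",
    "ConfigError",
    "read_pose_table",
    "write_pose_table",
    "read_event_log",
    "write_event_log",
    "load_config",
    "default_config",
]

#: Closed vocabulary of session-log event kinds. ``glitch`` records a rejected
#: (physically impossible) zone transition reported by the maze engine.
EVENT_KINDS = (
    "trigger",
    "stimulus",
    "reward",
    "poke",
    "door",
    "zone_entry",
    "zone_exit",
    "glitch",
)

DEFAULT_BODYPARTS = (
    "snout",
    "left_forepaw",
    "right_forepaw",
    "left_hindpaw_mid",
    "right_hindpaw_mid",
    "tail_base",
)


class PoseFormatError(ValueError):
    """Malformed pose-table layout (header rows, column structure)."""


class PoseParseError(ValueError):
    """A pose-table cell could not be parsed as a number."""


class EventLogError(ValueError):
    """Invalid event sequence or malformed event-log file."""


class ConfigError(ValueError):
    """Missing or invalid configuration keys."""


# ---------------------------------------------------------------------------
# Pose series
# ---------------------------------------------------------------------------


@dataclass
class PoseSeries:
    """Per-frame keypoint coordinates and likelihoods for named body parts.

    ``x``, ``y`` and ``likelihood`` are ``(n_frames, n_parts)`` float arrays;
    columns follow the order of :attr:`bodyparts`.
    """

    bodyparts: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    fps: float = 30.0
    frame_size: tuple[int, int] = (1100, 1100)
    timestamps: np.ndarray | None = None
    scorer: str = "virtual"

    def __post_init__(self) -> None:
        self.bodyparts = tuple(self.bodyparts)
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        self.likelihood = np.atleast_2d(np.asarray(self.likelihood, dtype=float))
        n, p = self.x.shape
        if self.y.shape != (n, p) or self.likelihood.shape != (n, p):
            raise ValueError("x, y and likelihood must share shape (n_frames, n_parts)")
        if p != len(self.bodyparts):
            raise ValueError("column count does not match bodypart list")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(n, dtype=float) / self.fps
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (n,):
                raise ValueError("timestamps length must equal frame count")
            if n > 1 and not np.all(np.diff(self.timestamps) > 0):
                raise ValueError("timestamps must be strictly increasing")
        if np.any((self.likelihood < 0) | (self.likelihood > 1)):
            raise ValueError("likelihood values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def frame_index(self) -> np.ndarray:
        return np.arange(self.n_frames)

    def part_index(self, name: str) -> int:
        try:
            return self.bodyparts.index(name)
        except ValueError:
            raise KeyError(f"unknown body part {name!r}") from None

    def part(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(x, y, likelihood)`` columns for one body part."""
        j = self.part_index(name)
        return self.x[:, j], self.y[:, j], self.likelihood[:, j]

    def slice(self, start: int, stop: int) -> "PoseSeries":
        return PoseSeries(
            bodyparts=self.bodyparts,
            x=self.x[start:stop],
            y=self.y[start:stop],
            likelihood=self.likelihood[start:stop],
            fps=self.fps,
            frame_size=self.frame_size,
            timestamps=self.timestamps[start:stop],
            scorer=self.scorer,
        )

    def validate_geometry(self) -> None:
        """Check that confidently tracked keypoints lie inside the frame."""
        w, h = self.frame_size
        conf = self.likelihood > 0
        if np.any(conf & ((self.x < 0) | (self.x >= w))):
            raise ValueError("x coordinate outside frame for likelihood > 0")
        if np.any(conf & ((self.y < 0) | (self.y >= h))):
            raise ValueError("y coordinate outside frame for likelihood > 0")

    def to_dataframe(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(
            [
                (self.scorer, bp, coord)
                for bp in self.bodyparts
                for coord in ("x", "y", "likelihood")
            ],
            names=["scorer", "bodyparts", "coords"],
        )
        n = self.n_frames
        data = np.empty((n, 3 * len(self.bodyparts)))
        for j in range(len(self.bodyparts)):
            data[:, 3 * j] = self.x[:, j]
            data[:, 3 * j + 1] = self.y[:, j]
            data[:, 3 * j + 2] = self.likelihood[:, j]
        return pd.DataFrame(data, columns=cols)


@dataclass
class FrameStack:
    """A stack of grayscale 8-bit frames with per-frame timestamps."""

    frames: np.ndarray  # (n, height, width), uint8
    timestamps: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n, height, width)")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.shape != (self.frames.shape[0],):
            raise ValueError("timestamps must align 1:1 with frames")

    @property
    def frame_size(self) -> tuple[int, int]:
        return (self.frames.shape[2], self.frames.shape[1])

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# Pose table reader / writer (three header rows: scorer / bodyparts / coords)
# ---------------------------------------------------------------------------

_COORDS = ("x", "y", "likelihood")


def write_pose_table(pose: PoseSeries, path: str | Path) -> None:
    """Write a pose series as CSV (or HDF5 for ``.h5``/``.hdf5`` suffixes).

    The CSV dialect has three header rows (scorer, bodyparts, coords) and one
    row per frame, matching the output of common markerless pose estimators.
    """
    path = Path(path)
    df = pose.to_dataframe()
    if path.suffix.lower() in (".h5", ".hdf5"):
        try:
            df.to_hdf(path, key="pose")
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise RuntimeError("HDF5 output requires PyTables") from exc
    else:
        df.to_csv(path, index=True, index_label=None)


def read_pose_table(
    path: str | Path,
    fps: float = 30.0,
    frame_size: tuple[int, int] = (1100, 1100),
) -> PoseSeries:
    """Read a three-header-row pose table (CSV, or HDF5 mirror).

    Timestamps are synthesized from the frame index at ``fps`` (the files do
    not carry wall-clock times). Raises :class:`PoseFormatError` for layout
    problems and :class:`PoseParseError` for non-numeric cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        df = pd.read_hdf(path, key="pose")
    else:
        try:
            df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        except (pd.errors.ParserError, ValueError) as exc:
            raise PoseFormatError(f"could not parse pose-table headers: {exc}") from exc
        if df.columns.nlevels != 3:
            raise PoseFormatError("expected three header rows (scorer/bodyparts/coords)")

    scorers = list(dict.fromkeys(df.columns.get_level_values(0)))
    if len(scorers) != 1:
        raise PoseFormatError(f"expected a single scorer in header row 1, got {scorers}")
    scorer = scorers[0]
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))

    bad = set(df.columns.get_level_values(2)) - set(_COORDS)
    if bad:
        raise PoseFormatError(
            f"header row 3 (coords) contains invalid entries {sorted(bad)}; "
            f"expected only {list(_COORDS)}"
        )
    for bp in bodyparts:
        have = set(df[scorer][bp].columns)
        missing = set(_COORDS) - have
        if missing:
            raise PoseFormatError(
                f"body part {bp!r} is missing column(s) {sorted(missing)} in header row 3"
            )

    n = len(df)
    p = len(bodyparts)
    x = np.empty((n, p))
    y = np.empty((n, p))
    lik = np.empty((n, p))
    for j, bp in enumerate(bodyparts):
        for coord, target in (("x", x), ("y", y), ("likelihood", lik)):
            col = pd.to_numeric(df[(scorer, bp, coord)], errors="coerce")
            if col.isna().any():
                frame = int(np.flatnonzero(col.isna().to_numpy())[0])
                raise PoseParseError(
                    f"non-numeric value for ({bp}, {coord}) at frame {frame}"
                )
            target[:, j] = col.to_numpy()
    return PoseSeries(
        bodyparts=tuple(bodyparts),
        x=x,
        y=y,
        likelihood=lik,
        fps=fps,
        frame_size=frame_size,
        scorer=scorer,
    )


# ---------------------------------------------------------------------------
# Event log
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventRecord:
    """One timestamped session event with a kind-specific payload."""

    time: float
    kind: str
    payload: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise EventLogError(f"event time must be non-negative, got {self.time}")
        if self.kind not in EVENT_KINDS:
            raise EventLogError(f"unknown event kind {self.kind!r}; allowed: {EVENT_KINDS}")
        object.__setattr__(self, "payload", dict(self.payload))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventRecord):
            return NotImplemented
        return (
            self.time == other.time
            and self.kind == other.kind
            and dict(self.payload) == dict(other.payload)
        )


def _check_sorted(events: Sequence[EventRecord]) -> None:
    times = [e.time for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise EventLogError("events must be sorted by time (ties keep input order)")


def write_event_log(events: Sequence[EventRecord], path: str | Path) -> None:
    """Write events as CSV (``time,kind,payload``) or JSON lines (``.jsonl``).

    Payloads are JSON-encoded with sorted keys so field order is stable and
    round trips are lossless.
    """
    events = list(events)
    _check_sorted(events)
    path = Path(path)
    if path.suffix.lower() == ".jsonl":
        with open(path, "w") as fh:
            for e in events:
                fh.write(
                    json.dumps(
                        {"time": e.time, "kind": e.kind, "payload": dict(e.payload)},
                        sort_keys=True,
                    )
                    + "\n"
                )
        return
    rows = [
        {"time": repr(float(e.time)), "kind": e.kind, "payload": json.dumps(dict(e.payload), sort_keys=True)}
        for e in events
    ]
    pd.DataFrame(rows, columns=["time", "kind", "payload"]).to_csv(path, index=False)


def read_event_log(path: str | Path) -> list[EventRecord]:
    """Read an event log written by :func:`write_event_log`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    events: list[EventRecord] = []
    if path.suffix.lower() == ".jsonl":
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                d = json.loads(line)
                events.append(EventRecord(float(d["time"]), d["kind"], d.get("payload", {})))
    else:
        df = pd.read_csv(path, dtype={"time": float, "kind": str, "payload": str})
        if list(df.columns) != ["time", "kind", "payload"]:
            raise EventLogError(f"unexpected event-log columns {list(df.columns)}")
        for _, row in df.iterrows():
            payload = json.loads(row["payload"]) if isinstance(row["payload"], str) else {}
            events.append(EventRecord(float(row["time"]), row["kind"], payload))
    _check_sorted(events)
    return events


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_REQUIRED_RIG_KEYS = ("platform_mm", "resolution", "fps", "scale_mm_per_px")
_REQUIRED_TRIGGER_KEYS = ("v_px", "t_s", "l_min", "refractory_s", "target")


@dataclass
class Config:
    """Declarative rig geometry, trigger parameters, protocols and seeds."""

    rig: dict
    trigger: dict
    protocols: dict
    seeds: dict

    def __post_init__(self) -> None:
        for key in _REQUIRED_RIG_KEYS:
            if key not in self.rig:
                raise ConfigError(f"rig config missing required key {key!r}")
        for key in _REQUIRED_TRIGGER_KEYS:
            if key not in self.trigger:
                raise ConfigError(f"trigger config missing required key {key!r}")
        if self.rig["fps"] <= 0:
            raise ConfigError("rig.fps must be > 0")
        if self.rig["scale_mm_per_px"] <= 0:
            raise ConfigError("rig.scale_mm_per_px must be > 0")

    def as_dict(self) -> dict:
        return {
            "rig": dict(self.rig),
            "trigger": dict(self.trigger),
            "protocols": dict(self.protocols),
            "seeds": dict(self.seeds),
        }


def default_config() -> Config:
    """Rig defaults: 0.55 m platform, 1100x1100 px camera at 30 fps, 0.45 mm/px."""
    return Config(
        rig={
            "platform_mm": [550.0, 550.0],
            "resolution": [1100, 1100],
            "fps": 30.0,
            "scale_mm_per_px": 0.45,
        },
        trigger={
            "v_px": 1.0,
            "t_s": 2.0,
            "l_min": 0.8,
            "refractory_s": 0.5,
            "target": "left_hindpaw_mid",
        },
        protocols={
            "arena": {"pulse_ms": 10.0, "intensity_mw_mm2": 40.0, "refractory_s": 600.0},
            "chambers": {
                "pulse_ms": 3.0,
                "per_mouse_isi_s": 60.0,
                "scheduler_refractory_s": 10.0,
                "idle_threshold": 30000.0,
                "idle_window_s": 2.0,
                "noise_floor": 10.0,
                "crop_px": 230,
            },
            "maze": {
                "pulse_ms": 3.0,
                "intensity_mw_mm2": 40.0,
                "left_hz": 5.0,
                "right_hz": 1.0,
                "reward_timeout_s": [45.0, 60.0],
            },
        },
        seeds={"master": 0},
    )


def load_config(path: str | Path) -> Config:
    """Load a YAML or TOML config file and validate its schema."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping at top level")
    try:
        return Config(
            rig=raw.get("rig", {}),
            trigger=raw.get("trigger", {}),
            protocols=raw.get("protocols", {}),
            seeds=raw.get("seeds", {}),
        )
    except KeyError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: Config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.as_dict(), fh, sort_keys=False)
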