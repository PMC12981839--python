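"""Alternation-maze task engine.

The maze is a single junction with one-way doors: mice enter through an
entry chamber and corridor, pass one-way into the junction, choose the left
or right corridor to reach that side's reward chamber, and can leave a
reward chamber only through a one-way exit door back toward the entry
corridor — so collecting consecutive rewards requires circling the maze.
Reward ports deliver on a nose poke only while armed; after a delivery a
port re-arms only once its timeout has elapsed *and* the mouse has exited
the reward chamber. Corridors can be paired with pulsed-laser stimulation at
per-corridor frequencies (fire on entry, then at the corridor's rate while
occupied).

Also here: trial segmentation (one trial per collected reward), the 2x2
side-transition matrix, and Euler-tour pseudorandomization of stimulus
conditions (a circuit over the complete directed graph of conditions, so
every ordered pair of distinct conditions occurs exactly once).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .core_io import EventRecord
from .virtual_rig import _require_seed

__all__ = [
    "MazeTopology",
    "PortState",
    "MazeState",
    "Trial",
    "default_topology",
    "zone_of",
    "maze_step",
    "CorridorStimulator",
    "segment_trials",
    "transition_matrix",
    "euler_tour_order",
    "simulate_maze_session",
    "MazeIntegrityError",
]

ZONES = (
    "entry_chamber",
    "entry_corridor",
    "junction",
    "left_corridor",
    "right_corridor",
    "left_reward",
    "right_reward",
)

REWARD_ZONE = {"left": "left_reward", "right": "right_reward"}
CORRIDOR_ZONE = {"left": "left_corridor", "right": "right_corridor"}


class MazeIntegrityError(ValueError):
    pass


@dataclass(frozen=True)
class MazeTopology:
    """Zone polygons and the directed transition graph of the one-way doors."""

    polygons: Mapping[str, Polygon]
    allowed: Mapping[str, frozenset[str]]

    def is_allowed(self, src: str, dst: str) -> bool:
        return dst == src or dst in self.allowed.get(src, frozenset())


def default_topology() -> MazeTopology:
    """Schematic maze layout in platform pixels (~0.45 mm/px).

    One-way doors sit at the junction entry and at the reward-chamber exits:
    the junction cannot be left backward into the entry corridor, and reward
    chambers exit only onto the return path toward the entry corridor.
    """
    def box(x0, y0, x1, y1):
        return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])

    polygons = {
        "entry_chamber": box(0, 180, 150, 320),
        "entry_corridor": box(150, 200, 450, 300),
        "junction": box(450, 200, 560, 300),
        "left_corridor": box(560, 20, 950, 160),
        "right_corridor": box(560, 340, 950, 480),
        "left_reward": box(950, 20, 1100, 160),
        "right_reward": box(950, 340, 1100, 480),
    }
    allowed = {
        "entry_chamber": frozenset({"entry_corridor"}),
        "entry_corridor": frozenset({"entry_chamber", "junction"}),
        "junction": frozenset({"left_corridor", "right_corridor"}),
        "left_corridor": frozenset({"junction", "left_reward"}),
        "right_corridor": frozenset({"junction", "right_reward"}),
        "left_reward": frozenset({"entry_corridor"}),
        "right_reward": frozenset({"entry_corridor"}),
    }
    return MazeTopology(polygons=polygons, allowed=allowed)


def zone_of(topology: MazeTopology, xy: tuple[float, float], previous: str | None = None) -> str | None:
    """Zone containing a point; falls back to the previous zone off-zone or on ties."""
    pt = Point(xy)
    matches = [z for z, poly in topology.polygons.items() if poly.covers(pt)]
    if len(matches) == 1:
        return matches[0]
    return previous


@dataclass
class PortState:
    """Reward-port arming logic: timeout plus required chamber exit."""

    timeout_s: float
    armed: bool = True
    last_reward_s: float | None = None
    requires_exit: bool = False
    exited_since_reward: bool = True

    def can_deliver(self) -> bool:
        return self.armed

    def deliver(self, t: float) -> None:
        self.armed = False
        self.last_reward_s = t
        self.requires_exit = True
        self.exited_since_reward = False

    def note_exit(self) -> None:
        self.exited_since_reward = True

    def maybe_rearm(self, t: float) -> None:
        if (not self.armed and self.last_reward_s is not None
                and t - self.last_reward_s >= self.timeout_s and self.exited_since_reward):
            self.armed = True
            self.requires_exit = False


@dataclass
class MazeState:
    zone: str
    time_s: float
    ports: dict[str, PortState]


def make_state(seed: int | np.random.Generator | None,
               timeout_range_s: tuple[float, float] = (45.0, 60.0),
               start_zone: str = "entry_chamber") -> MazeState:
    """Fresh session state; port timeouts drawn once per session from the range."""
    rng = _require_seed(seed)
    return MazeState(
        zone=start_zone,
        time_s=0.0,
        ports={side: PortState(timeout_s=float(rng.uniform(*timeout_range_s)))
               for side in ("left", "right")},
    )


def maze_step(
    state: MazeState,
    topology: MazeTopology,
    t: float,
    snout_xy: tuple[float, float] | None,
    pokes: Sequence[str] = (),
) -> list[EventRecord]:
    """Advance the maze engine by one frame.

    The snout keypoint determines zone membership (the poke sensor is
    nose-based); transitions are validated against the one-way graph, and a
    physically impossible jump is logged as a tracking glitch with the state
    unchanged. Pokes at an armed port deliver a reward and disarm it until
    the timeout elapses and the mouse has exited the chamber.
    """
    events: list[EventRecord] = []
    state.time_s = t
    if snout_xy is not None:
        new_zone = zone_of(topology, snout_xy, previous=state.zone)
        if new_zone is not None and new_zone != state.zone:
            if topology.is_allowed(state.zone, new_zone):
                events.append(EventRecord(t, "zone_exit", {"zone": state.zone}))
                events.append(EventRecord(t, "zone_entry", {"zone": new_zone}))
                for side, rz in REWARD_ZONE.items():
                    if state.zone == rz:
                        state.ports[side].note_exit()
                state.zone = new_zone
            else:
                events.append(EventRecord(t, "glitch", {
                    "from": state.zone, "to": new_zone}))
    for side in pokes:
        events.append(EventRecord(t, "poke", {"side": side}))
        port = state.ports[side]
        if port.can_deliver():
            port.deliver(t)
            events.append(EventRecord(t, "reward", {"side": side}))
    for port in state.ports.values():
        port.maybe_rearm(t)
    return events


class CorridorStimulator:
    """Frequency-paired corridor stimulation: fire on entry, then at the
    corridor's pulse rate while the mouse stays inside."""

    def __init__(self, corridor_hz: Mapping[str, float]):
        for zone, hz in corridor_hz.items():
            if hz <= 0:
                raise ValueError(f"protocol frequency must be positive ({zone}: {hz})")
        self.corridor_hz = dict(corridor_hz)
        self._inside: str | None = None
        self._next_fire: float = np.inf

    def step(self, t: float, zone: str, keypoint_xy: tuple[float, float] | None = None
             ) -> list[dict]:
        commands: list[dict] = []
        if zone in self.corridor_hz:
            if self._inside != zone:
                self._inside = zone
                self._next_fire = t  # fire on entry
            period = 1.0 / self.corridor_hz[zone]
            while t >= self._next_fire - 1e-9:
                commands.append({"time": t, "zone": zone, "target": keypoint_xy})
                self._next_fire += period
        else:
            self._inside = None
            self._next_fire = np.inf
        return commands


@dataclass(frozen=True)
class Trial:
    side: str
    corridor_entry_s: float
    reward_s: float
    n_stimuli: int

    def __post_init__(self) -> None:
        if self.reward_s <= self.corridor_entry_s:
            raise MazeIntegrityError("reward must follow corridor entry")


def segment_trials(events: Sequence[EventRecord], topology: MazeTopology | None = None
                   ) -> list[Trial]:
    """One trial per collected reward.

    The trial's corridor entry is the last entry into that side's corridor
    preceding the reward; aborted entries into the other corridor are
    ignored. A reward with no preceding corridor entry is an integrity
    error.
    """
    events = sorted(events, key=lambda e: e.time)
    trials: list[Trial] = []
    for k, ev in enumerate(events):
        if ev.kind != "reward":
            continue
        side = ev.payload["side"]
        corridor = CORRIDOR_ZONE[side]
        entry = None
        for prev in reversed(events[:k]):
            if prev.time > ev.time:
                continue
            if prev.kind == "zone_entry" and prev.payload.get("zone") == corridor:
                entry = prev.time
                break
        if entry is None:
            raise MazeIntegrityError(
                f"reward at t={ev.time} has no preceding {corridor} entry")
        n_stim = sum(1 for e in events
                     if e.kind == "stimulus" and entry <= e.time <= ev.time)
        trials.append(Trial(side=side, corridor_entry_s=entry, reward_s=ev.time,
                            n_stimuli=n_stim))
    return trials


def transition_matrix(trials: Sequence[Trial]) -> np.ndarray:
    """Row-normalized 2x2 matrix P(next side | current side), order (L, R)."""
    trials = list(trials)
    if len(trials) < 2:
        raise MazeIntegrityError("transition matrix undefined for < 2 trials")
    idx = {"left": 0, "right": 1}
    counts = np.zeros((2, 2))
    for a, b in zip(trials, trials[1:]):
        counts[idx[a.side], idx[b.side]] += 1
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        return np.where(sums > 0, counts / sums, np.nan)


def euler_tour_order(conditions: Sequence[object], seed: int | np.random.Generator | None
                     ) -> list[object]:
    """Stimulus sequence realizing an Eulerian circuit over condition pairs.

    On the complete directed graph over the distinct conditions (no
    self-loops), every ordered pair of distinct conditions appears exactly
    once as adjacent elements; sequence length is ``n(n-1) + 1``. Outgoing
    edges are consumed in seeded random order (Hierholzer's algorithm), so
    different seeds yield different but always-valid circuits.
    """
    conds = list(dict.fromkeys(conditions))
    n = len(conds)
    if n < 2:
        raise ValueError("Euler-tour ordering needs at least 2 distinct conditions")
    rng = _require_seed(seed)
    out_edges: dict[object, list[object]] = {}
    for u in conds:
        targets = [v for v in conds if v != u]
        rng.shuffle(targets)
        out_edges[u] = targets
    start = conds[int(rng.integers(n))]
    stack = [start]
    circuit: list[object] = []
    while stack:
        u = stack[-1]
        if out_edges[u]:
            stack.append(out_edges[u].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    assert len(circuit) == n * (n - 1) + 1
    return circuit


def simulate_maze_session(
    duration_s: float,
    seed: int | np.random.Generator | None,
    topology: MazeTopology | None = None,
    alternation_bias: float = 0.85,
    mean_zone_dwell_s: float = 2.0,
    poke_interval_s: float = 1.5,
    timeout_range_s: tuple[float, float] = (45.0, 60.0),
) -> tuple[list[EventRecord], MazeState]:
    """Scripted agent running the alternation task through the maze engine.

    The agent walks only allowed edges (it cannot pass one-way doors
    backward), pokes while dwelling in a reward chamber, and prefers the
    side opposite its previous reward with probability ``alternation_bias``.
    All port logic (timeout + required exit) is enforced by
    :func:`maze_step`; returns the event log and final state.
    """
    topology = topology or default_topology()
    rng = _require_seed(seed)
    state = make_state(rng, timeout_range_s=timeout_range_s)
    events: list[EventRecord] = []
    t = 0.0
    last_reward_side: str | None = None
    centroid = {z: topology.polygons[z].centroid.coords[0] for z in ZONES}

    def goto(zone: str) -> None:
        nonlocal t
        t += float(rng.exponential(mean_zone_dwell_s)) + 0.2
        events.extend(maze_step(state, topology, t, centroid[zone]))

    while t < duration_s:
        # circuit: entry corridor -> junction -> chosen corridor -> reward
        if state.zone == "entry_chamber":
            goto("entry_corridor")
            continue
        if state.zone == "entry_corridor":
            if rng.random() < 0.15:
                goto("entry_chamber")
            else:
                goto("junction")
            continue
        if state.zone == "junction":
            if last_reward_side is None:
                side = "left" if rng.random() < 0.5 else "right"
            else:
                opposite = "right" if last_reward_side == "left" else "left"
                side = opposite if rng.random() < alternation_bias else last_reward_side
            goto(CORRIDOR_ZONE[side])
            continue
        if state.zone in CORRIDOR_ZONE.values():
            side = "left" if state.zone == "left_corridor" else "right"
            if rng.random() < 0.08:
                goto("junction")  # aborted entry, back out through the open side
            else:
                goto(REWARD_ZONE[side])
            continue
        if state.zone in REWARD_ZONE.values():
            side = "left" if state.zone == "left_reward" else "right"
            # dwell and poke a few times
            n_pokes = 1 + int(rng.integers(3))
            rewarded = False
            for _ in range(n_pokes):
                t += poke_interval_s
                step_events = maze_step(state, topology, t, centroid[state.zone], pokes=[side])
                events.extend(step_events)
                if any(e.kind == "reward" for e in step_events):
                    rewarded = True
            if rewarded:
                last_reward_side = side
            goto("entry_corridor")  # one-way exit door
            continue
    return events, state
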