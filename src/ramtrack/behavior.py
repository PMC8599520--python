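"""Arm-access monitoring: the radial-arm-maze scoring state machine.

The machine consumes the tracked rat center once per sample tick and keeps:

* ``maze_state`` — 0 while the rat is on the central platform, else the
  1-based number of the arm currently occupied (``CurA``);
* ``af`` — per-arm food flags (1 = arm still baited); a baited arm's flag is
  cleared when the rat reaches the arm's distal food zone;
* ``entry`` — per-arm completed-entry counters;
* working-memory (short-term) errors — a re-entry into any arm already
  entered this session — and reference-memory (long-term) errors — the
  first entry into an arm that was never baited;
* latency bookkeeping: the session completes when no baited arm retains
  food (``max(af) == 0``).

Entry and exit are detected by the distance from the rat center to the arm's
proximal entry line, combined with a side-of-line test (the rat must actually
be on the arm side to enter, and on the platform side to exit).  The
side-of-line hysteresis prevents entry/exit chatter when the animal hovers on
the line.  Errors are scored at entry time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geometry import (
    N_PLATFORM_PIECES,
    SEGMENTS_PER_ARM,
    MazeGeometry,
    classify_point,
    distance_to_entry_line,
)
from .tracker import TargetPos

__all__ = ["TrackState", "BehaviorParams", "new_state", "update", "latency", "score_trajectory"]


@dataclass
class BehaviorParams:
    """Tunables of the entry/exit test.

    entry_distance_px: distance-to-entry-line threshold; default (None) is
        half the arm width in pixels.
    food_zone: arm segment index that counts as the food location (9 = distal).
    """

    entry_distance_px: float | None = None
    food_zone: int = SEGMENTS_PER_ARM - 1

    def resolve(self, geometry: MazeGeometry) -> float:
        d = self.entry_distance_px if self.entry_distance_px is not None else geometry.arm_width_px / 2
        if d <= 0:
            raise ValueError("entry_distance_px must be positive")
        return d


@dataclass
class TrackState:
    """Mutable session state (see module docstring)."""

    ever_baited: tuple[int, ...]  # immutable configured baited set, one flag per arm
    maze_state: int = 0  # 0 = platform, else 1-based arm number
    af: np.ndarray = field(default=None)  # type: ignore[assignment]
    entry: np.ndarray = field(default=None)  # type: ignore[assignment]
    short_term_errors: int = 0
    long_term_errors: int = 0
    start_time: float | None = None
    end_time: float | None = None
    complete: bool = False
    arm_sequence: list[int] = field(default_factory=list)  # 1-based, in entry order

    def __post_init__(self) -> None:
        n = len(self.ever_baited)
        if self.af is None:
            self.af = np.array(self.ever_baited, dtype=np.int8)
        if self.entry is None:
            self.entry = np.zeros(n, dtype=np.int64)


def new_state(geometry: MazeGeometry, baited_arms: Iterable[int]) -> TrackState:
    """Fresh session state.  ``baited_arms`` are 1-based arm numbers."""
    baited = sorted(set(int(a) for a in baited_arms))
    for a in baited:
        if not 1 <= a <= geometry.n_arms:
            raise ValueError(f"baited arm {a} out of range 1..{geometry.n_arms}")
    flags = tuple(1 if (k + 1) in baited else 0 for k in range(geometry.n_arms))
    return TrackState(ever_baited=flags)


def update(
    state: TrackState,
    pos: TargetPos,
    geometry: MazeGeometry,
    params: BehaviorParams | None = None,
) -> TrackState:
    """Advance the state machine by one tracked sample.  Mutates and returns
    ``state``; updates after completion are no-ops (the state is frozen)."""
    params = params or BehaviorParams()
    if state.complete:
        return state
    if state.start_time is None:
        state.start_time = pos.t
        if int(np.max(state.af, initial=0)) == 0:  # nothing baited: trivially done
            state.complete = True
            state.end_time = pos.t
            return state
    if not np.isfinite(pos.x) or not np.isfinite(pos.y):
        return state

    threshold = params.resolve(geometry)
    p = (pos.x, pos.y)

    if state.maze_state == 0:
        for k in range(geometry.n_arms):
            if distance_to_entry_line(geometry, k, p) >= threshold:
                continue
            u, v = geometry.arm_frame(k, np.array([pos.x]), np.array([pos.y]))
            on_arm_side = u[0] > geometry.junction_offset_px and abs(v[0]) <= geometry.arm_width_px / 2
            if not on_arm_side:
                continue
            # entry event into arm k+1
            if state.entry[k] > 0:
                state.short_term_errors += 1
            elif state.ever_baited[k] == 0:
                state.long_term_errors += 1
            state.entry[k] += 1
            state.maze_state = k + 1
            state.arm_sequence.append(k + 1)
            break
    else:
        k = state.maze_state - 1
        if state.af[k] == 1:
            cls = classify_point(geometry, p)
            if cls.region == "arm" and cls.arm_index == k:
                seg = (
                    cls.zone_id - (N_PLATFORM_PIECES + k * SEGMENTS_PER_ARM)
                    if cls.zone_id is not None
                    else -1
                )
                if seg >= params.food_zone:
                    state.af[k] = 0  # food taken
        if distance_to_entry_line(geometry, k, p) < threshold:
            u, _ = geometry.arm_frame(k, np.array([pos.x]), np.array([pos.y]))
            if u[0] <= geometry.junction_offset_px:  # platform side: exit event
                state.maze_state = 0

    if int(np.max(state.af, initial=0)) == 0 and not state.complete:
        state.complete = True
        state.end_time = pos.t
    return state


def latency(state: TrackState) -> float:
    """Seconds from session start until the last baited arm was emptied."""
    if not state.complete or state.end_time is None or state.start_time is None:
        raise ValueError("session not complete: latency undefined")
    return state.end_time - state.start_time


def score_trajectory(
    traj: Sequence[TargetPos],
    geometry: MazeGeometry,
    baited_arms: Iterable[int],
    params: BehaviorParams | None = None,
) -> TrackState:
    """Run the state machine over a full trajectory and return the final state."""
    state = new_state(geometry, baited_arms)
    for pos in traj:
        update(state, pos, geometry, params)
    return state
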