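"""Ground-truthed synthetic infrared maze scenes.

Generates the kind of footage the tracker is built for, with exact ground
truth: a dark background, a bright rat blob (an ellipse oriented along its
motion, gray level above the binarization threshold), small bright dropping
spots deposited along the animal's path that persist for the rest of the
session, optional bright clutter outside the maze footprint, and an optional
bright intruder (a leg/shoe-like strip entering from the image edge over one
arm, or a large occluder covering part of the maze).

Everything is deterministic given the scene seed.  Frames are 8-bit
grayscale; the generator exposes both a materialized ``render_scene`` (small
scenes, tests) and a streaming ``iter_frames`` (long robustness runs).

The scene scale mirrors a typical overhead IR recording of an 8-arm maze:
a 480×480 working subimage at 0.4 cm/px, a ~12×6 cm rat at gray 200 on a
gray-40 background, travel speeds around 12 cm/s with pauses of a few
seconds at food sites, and 2–8 px droppings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from . import behavior, metrics, tracker
from .geometry import MazeGeometry, build_geometry, classify_point, classify_points

__all__ = [
    "RatConfig",
    "DroppingsConfig",
    "IntruderConfig",
    "SceneConfig",
    "Event",
    "GroundTruth",
    "ScriptedPath",
    "scripted_path",
    "session_waypoints",
    "render_scene",
    "iter_frames",
    "run_case",
    "CaseResult",
    "case1_scene",
    "case2_scene",
]


@dataclass(frozen=True)
class RatConfig:
    major_axis_px: float = 30.0
    minor_axis_px: float = 15.0
    gray: int = 200


@dataclass(frozen=True)
class DroppingsConfig:
    count: int = 10
    size_range_px: tuple[int, int] = (2, 4)  # spot diameters; <5 px vanish under the 5×5 opening
    gray: int = 200


@dataclass(frozen=True)
class IntruderConfig:
    """Bright intruder entering the scene.

    ``kind='strip'``: a leg/shoe-like rectangle (``span_px`` long across the
    arm direction, ``width_px`` deep along it) that enters from the image
    edge along one arm's axis, steps briefly all the way onto the arm (the
    crossing), then rests covering only the outermost ``dwell_depth_px`` of
    the arm before leaving.  ``kind='occluder'``: a half-plane-like block
    covering the distal part of the arm and its surroundings for the whole
    presence block.
    """

    kind: str = "strip"  # "strip" | "occluder"
    arm: int = 0
    width_px: float = 40.0
    span_px: float = 200.0
    gray: int = 220
    start_frame: int = 0
    n_frames: int = 0
    enter_s: float = 2.0
    cross_s: float = 2.0
    dwell_depth_px: float = 10.0
    cross_depth_px: float = 60.0


@dataclass(frozen=True)
class Event:
    frame: int
    t: float
    kind: str  # "entry" | "exit" | "food" | "pause_start" | "pause_end"
    arm: int | None = None  # 0-based arm index for entry/exit/food


@dataclass
class ScriptedPath:
    """Constant-speed interpolated path with a classification-derived event log."""

    t: np.ndarray
    positions: np.ndarray  # (n, 2) px
    headings: np.ndarray  # radians
    events: list[Event]


@dataclass
class SceneConfig:
    geometry: MazeGeometry = field(default_factory=build_geometry)
    fps: float = 10.0
    duration_s: float = 60.0
    rat: RatConfig = field(default_factory=RatConfig)
    waypoints: Sequence[tuple[float, float]] = ()
    speeds_cm_s: Sequence[float] | float = 12.0
    pauses_s: Sequence[float] | float = 0.0
    droppings: DroppingsConfig | None = field(default_factory=DroppingsConfig)
    intruder: IntruderConfig | None = None
    background_gray: int = 40
    clutter: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_gray >= 128:
            raise ValueError("background must binarize to 0 (gray < 128)")
        if self.rat.gray <= 127:
            raise ValueError("rat gray level must exceed the 127 threshold")
        if not self.waypoints:
            self.waypoints = (self.geometry.center,)

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))


@dataclass
class GroundTruth:
    """Per-frame truth for a rendered scene."""

    t: np.ndarray
    centers: np.ndarray  # (n, 2)
    headings: np.ndarray
    rat: RatConfig
    events: list[Event]
    dropping_spots: list[tuple[int, float, float, int]]  # (deposit frame, x, y, size px)
    intruder_present: np.ndarray  # bool per frame

    def point_on_rat(self, i: int, x: float, y: float) -> bool:
        """Whether (x, y) lies on the rat's true elliptical body in frame i."""
        cx, cy = self.centers[i]
        th = self.headings[i]
        dx, dy = x - cx, y - cy
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        a = self.rat.major_axis_px / 2
        b = self.rat.minor_axis_px / 2
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def rat_mask(self, i: int, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, bool)
        _fill_ellipse(out, self.centers[i], self.headings[i], self.rat, value=True)
        return out


# ---------------------------------------------------------------------------
# path scripting


def scripted_path(
    geometry: MazeGeometry,
    waypoints: Sequence[tuple[float, float]],
    speeds_cm_s: Sequence[float] | float,
    fps: float,
    pauses_s: Sequence[float] | float = 0.0,
    duration_s: float | None = None,
) -> ScriptedPath:
    """Constant-speed linear interpolation through waypoints (px), sampled at
    frame times 0, 1/fps, …  ``speeds_cm_s`` applies per leg (scalar = all
    legs); ``pauses_s`` is the dwell after arriving at each waypoint.  If
    ``duration_s`` exceeds the itinerary the animal rests at the final
    waypoint; if shorter, the itinerary is truncated.
    """
    wps = np.asarray(waypoints, float)
    if wps.ndim != 2 or wps.shape[0] < 1:
        raise ValueError("need at least one waypoint")
    for wx, wy in wps:
        if classify_point(geometry, (wx, wy)).region == "outside":
            raise ValueError(f"waypoint ({wx:.1f}, {wy:.1f}) lies outside the maze footprint")
    n_legs = wps.shape[0] - 1
    speeds = np.broadcast_to(np.asarray(speeds_cm_s, float).ravel(), (max(n_legs, 1),)) \
        if np.ndim(speeds_cm_s) == 0 or len(np.atleast_1d(speeds_cm_s)) == 1 \
        else np.asarray(speeds_cm_s, float)
    pauses = np.broadcast_to(np.asarray(pauses_s, float).ravel(), (wps.shape[0],)) \
        if np.ndim(pauses_s) == 0 or len(np.atleast_1d(pauses_s)) == 1 \
        else np.asarray(pauses_s, float)
    if n_legs and speeds.shape[0] != n_legs:
        raise ValueError("speeds length must match the number of legs")
    if np.any(speeds <= 0):
        raise ValueError("speeds must be positive")
    if pauses.shape[0] != wps.shape[0]:
        raise ValueError("pauses length must match the number of waypoints")

    # itinerary: (t_start, t_end, p0, p1) motion legs and pause intervals
    segs: list[tuple[float, float, np.ndarray, np.ndarray]] = []
    pause_spans: list[tuple[float, float]] = []
    t0 = 0.0
    if pauses[0] > 0:
        pause_spans.append((t0, t0 + pauses[0]))
        t0 += pauses[0]
    for leg in range(n_legs):
        d_cm = float(np.hypot(*(wps[leg + 1] - wps[leg]))) * geometry.cm_per_px
        dt = d_cm / speeds[leg]
        if dt > 0:
            segs.append((t0, t0 + dt, wps[leg], wps[leg + 1]))
            t0 += dt
        if pauses[leg + 1] > 0:
            pause_spans.append((t0, t0 + pauses[leg + 1]))
            t0 += pauses[leg + 1]
    total = t0 if duration_s is None else duration_s
    n = int(math.floor(total * fps + 1e-9)) + 1 if duration_s is None else int(round(total * fps))
    n = max(n, 1)
    t = np.arange(n) / fps

    pos = np.empty((n, 2))
    heading = np.zeros(n)
    last_head = 0.0
    if n_legs:
        v0 = wps[1] - wps[0]
        last_head = math.atan2(v0[1], v0[0])
    si = 0
    for i, ti in enumerate(t):
        while si < len(segs) and ti > segs[si][1] + 1e-12:
            si += 1
        if si < len(segs) and ti >= segs[si][0] - 1e-12:
            ts, te, p0, p1 = segs[si]
            f = 0.0 if te == ts else min(1.0, max(0.0, (ti - ts) / (te - ts)))
            pos[i] = p0 + f * (p1 - p0)
            last_head = math.atan2(p1[1] - p0[1], p1[0] - p0[0])
        elif si < len(segs):
            pos[i] = segs[si][2]  # pausing before this leg starts
        else:
            pos[i] = segs[-1][3] if segs else wps[0]
        heading[i] = last_head

    events = _derive_events(geometry, t, pos, pause_spans, total)
    return ScriptedPath(t=t, positions=pos, headings=heading, events=events)


def _derive_events(
    geometry: MazeGeometry,
    t: np.ndarray,
    pos: np.ndarray,
    pause_spans: list[tuple[float, float]],
    total: float,
) -> list[Event]:
    """Event log from pure region classification of the true positions."""
    region, arm, zone = classify_points(geometry, pos[:, 0], pos[:, 1])
    events: list[Event] = []
    cur_arm = int(arm[0])
    food_seen: set[int] = set()
    for i in range(len(t)):
        a = int(arm[i])
        if a != cur_arm:
            if cur_arm >= 0:
                events.append(Event(i, float(t[i]), "exit", cur_arm))
            if a >= 0:
                events.append(Event(i, float(t[i]), "entry", a))
                food_seen.discard(a)
            cur_arm = a
        if a >= 0 and a not in food_seen:
            seg = int(zone[i]) - (9 + a * 10)
            if seg == 9:
                events.append(Event(i, float(t[i]), "food", a))
                food_seen.add(a)
    if len(pause_spans) == 0 and len(pos) > 0 and np.allclose(pos, pos[0]):
        pause_spans = [(float(t[0]), total)]
    for ps, pe in pause_spans:
        i0 = int(np.searchsorted(t, ps - 1e-9))
        i1 = min(int(np.searchsorted(t, pe - 1e-9)), len(t) - 1)
        if i0 < len(t):
            events.append(Event(i0, float(t[i0]), "pause_start"))
            events.append(Event(i1, float(t[i1]), "pause_end"))
    events.sort(key=lambda e: (e.frame, e.kind))
    return events


def session_waypoints(
    geometry: MazeGeometry, arm_visits: Sequence[int], food_pause_s: float = 3.0
) -> tuple[list[tuple[float, float]], list[float]]:
    """Center ↔ food-zone itinerary visiting ``arm_visits`` (1-based arm
    numbers) in order; returns (waypoints, per-waypoint pauses)."""
    wps: list[tuple[float, float]] = [geometry.center]
    pauses: list[float] = [0.0]
    for a in arm_visits:
        wps.append(geometry.food_zone_center(a - 1))
        pauses.append(food_pause_s)
        wps.append(geometry.center)
        pauses.append(0.0)
    return wps, pauses


# ---------------------------------------------------------------------------
# rendering


def _fill_ellipse(img: np.ndarray, center, theta: float, rat: RatConfig, value) -> None:
    a, b = rat.major_axis_px / 2, rat.minor_axis_px / 2
    cx, cy = float(center[0]), float(center[1])
    r = int(math.ceil(max(a, b))) + 1
    h, w = img.shape
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs, ys = np.meshgrid(np.arange(x0, x1, dtype=float), np.arange(y0, y1, dtype=float))
    dx, dy = xs - cx, ys - cy
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    img[y0:y1, x0:x1][inside] = value


def _fill_disc(img: np.ndarray, x: float, y: float, diameter: float, value) -> None:
    r = diameter / 2
    h, w = img.shape
    x0, x1 = max(0, int(x - r) - 1), min(w, int(x + r) + 2)
    y0, y1 = max(0, int(y - r) - 1), min(h, int(y + r) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    xs, ys = np.meshgrid(np.arange(x0, x1, dtype=float), np.arange(y0, y1, dtype=float))
    inside = (xs - x) ** 2 + (ys - y) ** 2 <= r * r
    img[y0:y1, x0:x1][inside] = value


def _fill_arm_frame_rect(
    img: np.ndarray, geometry: MazeGeometry, arm: int, u0: float, u1: float, v_half: float, value
) -> None:
    """Fill the rectangle u∈[u0,u1], |v|≤v_half of an arm's frame."""
    h, w = img.shape
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    u, v = geometry.arm_frame(arm, xs.ravel(), ys.ravel())
    inside = (u >= u0) & (u <= u1) & (np.abs(v) <= v_half)
    img.ravel()[inside] = value


def _clutter_boxes(geometry: MazeGeometry) -> list[tuple[int, int, int, int]]:
    # bright static structures wholly outside the footprint (cage edges, cables)
    w, h = geometry.image_size
    return [(8, 8, 40, 32), (w - 46, 12, 38, 26), (10, h - 40, 50, 24)]


def _intruder_front(cfg: IntruderConfig, geometry: MazeGeometry, frame: int, fps: float) -> float | None:
    """Leading-edge position u0 (arm-frame px) of the strip in this frame, or
    None when absent."""
    j = frame - cfg.start_frame
    if j < 0 or j >= cfg.n_frames:
        return None
    tip_u = geometry.junction_offset_px + geometry.arm_length_px
    u_edge = tip_u + cfg.width_px  # fully beyond the arm, at the image border
    u_dwell = tip_u - cfg.dwell_depth_px
    u_cross = tip_u - cfg.cross_depth_px
    tj = j / fps
    t_total = cfg.n_frames / fps
    if cfg.kind == "occluder":
        return u_cross
    t_cross0 = t_total / 2 - cfg.cross_s / 2
    if tj < cfg.enter_s:
        f = tj / cfg.enter_s
        return u_edge + f * (u_dwell - u_edge)
    if tj > t_total - cfg.enter_s:
        f = (t_total - tj) / cfg.enter_s
        return u_edge + f * (u_dwell - u_edge)
    if t_cross0 <= tj <= t_cross0 + cfg.cross_s:
        # step across the arm and back: triangular excursion to u_cross
        f = (tj - t_cross0) / cfg.cross_s
        depth = 1 - abs(2 * f - 1)
        return u_dwell + depth * (u_cross - u_dwell)
    return u_dwell


def ground_truth(config: SceneConfig) -> GroundTruth:
    """Deterministic truth (positions, droppings, events) for a scene."""
    path = scripted_path(
        config.geometry,
        config.waypoints,
        config.speeds_cm_s,
        config.fps,
        config.pauses_s,
        duration_s=config.duration_s,
    )
    n = config.n_frames
    spots: list[tuple[int, float, float, int]] = []
    if config.droppings is not None and config.droppings.count > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD50]))
        frames = np.sort(rng.integers(0, n, size=config.droppings.count))
        lo, hi = config.droppings.size_range_px
        for f in frames:
            x, y = path.positions[f]
            # offset behind/next to the animal, kept inside the footprint
            for _ in range(8):
                ang = rng.uniform(0, 2 * math.pi)
                r = rng.uniform(8, 20)
                px, py = x + r * math.cos(ang), y + r * math.sin(ang)
                if classify_point(config.geometry, (px, py)).region != "outside":
                    break
            else:
                px, py = x, y
            size = int(rng.integers(lo, hi + 1))
            spots.append((int(f), float(px), float(py), size))
    present = np.zeros(n, bool)
    if config.intruder is not None:
        for i in range(n):
            present[i] = _intruder_front(config.intruder, config.geometry, i, config.fps) is not None
    return GroundTruth(
        t=path.t,
        centers=path.positions,
        headings=path.headings,
        rat=config.rat,
        events=path.events,
        dropping_spots=spots,
        intruder_present=present,
    )


def iter_frames(
    config: SceneConfig, truth: GroundTruth | None = None
) -> Iterator[tuple[float, np.ndarray]]:
    """Stream ``(t, frame)`` pairs for a scene; frames are 8-bit grayscale."""
    truth = truth if truth is not None else ground_truth(config)
    geo = config.geometry
    w, h = geo.image_size
    base = np.full((h, w), config.background_gray, np.uint8)
    if config.clutter:
        for bx, by, bw, bh in _clutter_boxes(geo):
            base[by : by + bh, bx : bx + bw] = 180
    deposited = 0
    spots = truth.dropping_spots
    for i in range(config.n_frames):
        while deposited < len(spots) and spots[deposited][0] <= i:
            _, sx, sy, size = spots[deposited]
            _fill_disc(base, sx, sy, float(size), np.uint8(200 if config.droppings is None else config.droppings.gray))
            deposited += 1
        frame = base.copy()
        if config.intruder is not None:
            u0 = _intruder_front(config.intruder, geo, i, config.fps)
            if u0 is not None:
                cfg = config.intruder
                u1 = u0 + (cfg.width_px if cfg.kind == "strip" else 1e4)
                _fill_arm_frame_rect(frame, geo, cfg.arm, u0, u1, cfg.span_px / 2, np.uint8(cfg.gray))
        _fill_ellipse(frame, truth.centers[i], truth.headings[i], config.rat, np.uint8(config.rat.gray))
        yield float(truth.t[i]), frame


def render_scene(config: SceneConfig) -> tuple[list[np.ndarray], GroundTruth]:
    """Materialize every frame of a (small) scene plus its ground truth."""
    truth = ground_truth(config)
    frames = [f for _, f in iter_frames(config, truth)]
    return frames, truth


# ---------------------------------------------------------------------------
# robustness cases


@dataclass
class CaseResult:
    detection_rate_pct: float
    n_frames: int
    trajectory: metrics.Trajectory
    state: behavior.TrackState
    report: metrics.SessionReport
    truth: GroundTruth


def run_case(
    config: SceneConfig,
    params: tracker.TrackerParams | None = None,
    baited_arms: Sequence[int] = (2, 4, 6, 8),
) -> CaseResult:
    """Render a scene, track every frame, score the detection rate against the
    true body extent, and build the full session report.

    A frame counts as detected when the tracker reports a position and that
    position lies on the animal's true elliptical body in that frame.
    """
    params = params or tracker.TrackerParams(sample_period=1.0 / config.fps)
    truth = ground_truth(config)
    points: list[tracker.TargetPos] = []
    last: tracker.TargetPos | None = None
    hits = 0
    for i, (t, frame) in enumerate(iter_frames(config, truth)):
        res = tracker.locate_rat(frame, config.geometry, params, t=t)
        if res.found:
            pos = res
            last = res
            if truth.point_on_rat(i, res.x, res.y):
                hits += 1
        elif last is not None:
            pos = tracker.TargetPos(t, last.x, last.y, False, "carried-forward")
        else:
            pos = res
        points.append(pos)
    n = len(points)
    traj = metrics.Trajectory.from_points(
        points, config.geometry.cm_per_px, sample_period=1.0 / config.fps
    )
    state = behavior.score_trajectory(points, config.geometry, baited_arms)
    report = metrics.build_report(traj, state, config.geometry)
    return CaseResult(
        detection_rate_pct=100.0 * hits / n,
        n_frames=n,
        trajectory=traj,
        state=state,
        report=report,
        truth=truth,
    )


_CASE_ARM_VISITS = (4, 2, 7, 4, 6, 8, 1, 6, 2, 8, 5, 4)


def _case_base(seed: int, duration_s: float, fps: float) -> SceneConfig:
    geo = build_geometry()
    wps, pauses = session_waypoints(geo, _CASE_ARM_VISITS, food_pause_s=4.0)
    return SceneConfig(
        geometry=geo,
        fps=fps,
        duration_s=duration_s,
        waypoints=wps,
        speeds_cm_s=12.0,
        pauses_s=pauses,
        droppings=DroppingsConfig(count=10, size_range_px=(2, 8)),
        clutter=True,
        seed=seed,
    )


def case1_scene(seed: int = 0, duration_s: float = 300.0, fps: float = 10.0) -> SceneConfig:
    """Robustness Case 1: a 5-minute-equivalent session with 10 persistent
    dropping spots (2–8 px) and out-of-maze clutter, no intruder."""
    return _case_base(seed, duration_s, fps)


def case2_scene(seed: int = 0, duration_s: float = 300.0, fps: float = 10.0) -> SceneConfig:
    """Robustness Case 2: the Case-1 scene plus a leg/shoe-like intruder strip
    present for 25% of the frames, stepping across one arm once."""
    cfg = _case_base(seed, duration_s, fps)
    n = cfg.n_frames
    intruder = IntruderConfig(
        kind="strip",
        arm=0,
        start_frame=int(0.35 * n),
        n_frames=int(0.25 * n),
    )
    return replace(cfg, intruder=intruder)
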