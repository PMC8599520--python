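"""Trajectory-level cognitive quantities.

Computes the session summary reported after a maze test: food-search path
length, average speed, per-region dwell-time percentages, "S spots" (places
where the animal stays still), and the per-zone dot histogram used for
occupancy heatmaps.

Conventions:

* the trajectory samples are the logged rat centers, one per sample tick
  (nominally every 0.05 s); the "dots" of the occupancy statistics are these
  samples themselves;
* samples flagged carried-forward are included in dwell-time fractions (the
  animal is somewhere) but, being copies of the last found position, they
  contribute zero displacement to path length;
* dwell-time percentages use the full session duration (sample count) as the
  denominator, so samples classified outside the footprint make the three
  region percentages sum to less than 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import behavior
from .geometry import MazeGeometry, classify_points
from .tracker import TargetPos

__all__ = [
    "Trajectory",
    "SSpot",
    "SessionReport",
    "path_length",
    "average_speed",
    "region_time_fractions",
    "detect_s_spots",
    "zone_histogram",
    "build_report",
]


@dataclass
class Trajectory:
    """Time-ordered rat centers with the pixel scale needed for metric units."""

    t: np.ndarray  # seconds
    x: np.ndarray  # px
    y: np.ndarray  # px
    found: np.ndarray  # bool per sample
    source: list[str]
    cm_per_px: float
    sample_period: float = 0.05

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.found = np.asarray(self.found, bool)
        n = self.t.size
        if not (self.x.size == self.y.size == self.found.size == len(self.source) == n):
            raise ValueError("trajectory arrays must have equal length")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) > 1 else 0.0

    @classmethod
    def from_points(
        cls, points: Sequence[TargetPos], cm_per_px: float, sample_period: float = 0.05
    ) -> "Trajectory":
        return cls(
            t=np.array([p.t for p in points]),
            x=np.array([p.x for p in points]),
            y=np.array([p.y for p in points]),
            found=np.array([p.found for p in points]),
            source=[p.source for p in points],
            cm_per_px=cm_per_px,
            sample_period=sample_period,
        )

    def points(self) -> list[TargetPos]:
        return [
            TargetPos(float(t), float(x), float(y), bool(f), s)
            for t, x, y, f, s in zip(self.t, self.x, self.y, self.found, self.source)
        ]

    def to_dataframe(self, geometry: MazeGeometry | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t_s": self.t,
                "x_px": self.x,
                "y_px": self.y,
                "x_cm": self.x * self.cm_per_px,
                "y_cm": self.y * self.cm_per_px,
                "found": self.found.astype(int),
                "source": self.source,
            }
        )
        if geometry is not None:
            region, arm, zone = classify_points(geometry, np.nan_to_num(self.x), np.nan_to_num(self.y))
            tags = np.array(["outside", "platform", "arm"], dtype=object)[region + 1]
            df["region"] = tags
            df["zone_id"] = zone
        return df


@dataclass(frozen=True)
class SSpot:
    """A stillness episode: all movement confined within a small radius."""

    center: tuple[float, float]  # px, anchor sample
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SessionReport:
    """All per-session cognitive quantities."""

    latency_s: float | None
    short_term_errors: int
    long_term_errors: int
    path_length_m: float
    avg_speed_cm_s: float
    pct_time_platform: float
    pct_time_baited_arms: float
    pct_time_nonbaited_arms: float
    n_s_spots: int
    s_spot_duration_s: float
    entries: tuple[int, ...]
    arm_sequence: tuple[int, ...]
    complete: bool = True

    def to_series(self) -> pd.Series:
        d = {
            "latency_s": self.latency_s,
            "short_term_errors": self.short_term_errors,
            "long_term_errors": self.long_term_errors,
            "path_length_m": self.path_length_m,
            "avg_speed_cm_s": self.avg_speed_cm_s,
            "pct_time_platform": self.pct_time_platform,
            "pct_time_baited_arms": self.pct_time_baited_arms,
            "pct_time_nonbaited_arms": self.pct_time_nonbaited_arms,
            "n_s_spots": self.n_s_spots,
            "s_spot_duration_s": self.s_spot_duration_s,
            "complete": self.complete,
            "arm_sequence": " ".join(map(str, self.arm_sequence)),
        }
        for k, e in enumerate(self.entries):
            d[f"entries_arm_{k + 1}"] = e
        return pd.Series(d)


def _valid_xy(traj: Trajectory) -> np.ndarray:
    return np.isfinite(traj.x) & np.isfinite(traj.y)


def path_length(traj: Trajectory) -> float:
    """Food-search path length in meters: sum of consecutive dot distances."""
    ok = _valid_xy(traj)
    x, y = traj.x[ok], traj.y[ok]
    if x.size < 2:
        return 0.0
    steps = np.hypot(np.diff(x), np.diff(y))
    return float(steps.sum() * traj.cm_per_px / 100.0)


def average_speed(traj: Trajectory) -> float:
    """Mean travel speed in cm/s over the session."""
    if traj.duration <= 0:
        raise ValueError("average speed undefined for zero-duration trajectory")
    return path_length(traj) * 100.0 / traj.duration


def region_time_fractions(
    traj: Trajectory, geometry: MazeGeometry, baited_arms: Iterable[int]
) -> tuple[float, float, float]:
    """(platform %, baited-arm %, non-baited-arm %) of session samples."""
    baited = {int(a) - 1 for a in baited_arms}
    ok = _valid_xy(traj)
    n = len(traj)
    if n == 0:
        return (0.0, 0.0, 0.0)
    region, arm, _ = classify_points(geometry, traj.x[ok], traj.y[ok])
    plat = int(np.sum(region == 0))
    in_arm = region == 1
    n_baited = int(sum(1 for a in arm[in_arm] if int(a) in baited))
    n_nonbaited = int(np.sum(in_arm)) - n_baited
    return (100.0 * plat / n, 100.0 * n_baited / n, 100.0 * n_nonbaited / n)


def detect_s_spots(
    traj: Trajectory, radius_cm: float = 2.5, min_duration_s: float = 2.0
) -> list[SSpot]:
    """Stillness episodes: greedy anchored scan.

    A spot opens at sample i if every sample within the next
    ``min_duration_s`` stays within ``radius_cm`` of sample i; it then
    extends while samples remain within that radius of the anchor.  Scanning
    resumes after the spot ends, so spots never overlap.
    """
    if radius_cm <= 0 or min_duration_s <= 0:
        raise ValueError("radius_cm and min_duration_s must be positive")
    n = len(traj)
    r_px = radius_cm / traj.cm_per_px
    spots: list[SSpot] = []
    i = 0
    while i < n:
        if not (np.isfinite(traj.x[i]) and np.isfinite(traj.y[i])):
            i += 1
            continue
        d = np.hypot(traj.x[i:] - traj.x[i], traj.y[i:] - traj.y[i])
        out = np.nonzero(~(d <= r_px))[0]
        j_end = i + (out[0] if out.size else d.size)  # first sample beyond radius
        if traj.t[j_end - 1] - traj.t[i] >= min_duration_s:
            spots.append(
                SSpot(
                    center=(float(traj.x[i]), float(traj.y[i])),
                    start=float(traj.t[i]),
                    end=float(traj.t[j_end - 1]),
                )
            )
            i = j_end
        else:
            i += 1
    return spots


def zone_histogram(traj: Trajectory, geometry: MazeGeometry) -> np.ndarray:
    """Per-zone sample counts (length ``geometry.n_zones``); the dots of the
    occupancy statistics are the trajectory samples themselves."""
    ok = _valid_xy(traj)
    _, _, zone = classify_points(geometry, traj.x[ok], traj.y[ok])
    inside = zone[zone >= 0]
    return np.bincount(inside, minlength=geometry.n_zones).astype(np.int64)


def build_report(
    traj: Trajectory,
    state: behavior.TrackState,
    geometry: MazeGeometry,
    s_spot_radius_cm: float = 2.5,
    s_spot_min_duration_s: float = 2.0,
) -> SessionReport:
    """Assemble the full session summary from a trajectory and final state."""
    baited = [k + 1 for k, b in enumerate(state.ever_baited) if b]
    plat, in_baited, in_nonbaited = region_time_fractions(traj, geometry, baited)
    spots = detect_s_spots(traj, s_spot_radius_cm, s_spot_min_duration_s)
    lat = behavior.latency(state) if state.complete else None
    return SessionReport(
        latency_s=lat,
        short_term_errors=state.short_term_errors,
        long_term_errors=state.long_term_errors,
        path_length_m=path_length(traj),
        avg_speed_cm_s=average_speed(traj) if traj.duration > 0 else 0.0,
        pct_time_platform=plat,
        pct_time_baited_arms=in_baited,
        pct_time_nonbaited_arms=in_nonbaited,
        n_s_spots=len(spots),
        s_spot_duration_s=float(sum(s.duration for s in spots)),
        entries=tuple(int(e) for e in state.entry),
        arm_sequence=tuple(state.arm_sequence),
        complete=state.complete,
    )
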