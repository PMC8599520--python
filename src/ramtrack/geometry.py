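"""Pixel-space model of the radial arm maze.

The maze is a central circular platform with ``n_arms`` rectangular arms
radiating from it (default eight arms at 45° spacing, each 70 cm long and
10 cm wide).  The model provides:

* the filled binary footprint mask used by the tracker,
* one entry line per arm across its proximal (platform-side) end,
* an 89-piece statistical partition (for the default maze): each arm is cut
  into 10 segments of 70 cm² along its axis, and the platform is cut into 9
  pieces of ≈70 cm² (a central disc plus eight annular sectors),
* fast point classification against regions and zones.

Coordinates are ``(x, y)`` = ``(col, row)`` pixels, 0-based, origin at the
top-left of the working subimage; angles are radians measured from the +x
axis toward +y (i.e. clockwise on screen).

Geometry of the junction: an arm rectangle starts at the chord offset
``x_j = sqrt(R² − (W/2)²)`` from the center so that the arm meets the
platform rim at full width.  The lens-shaped overlap of the rectangle with
the platform disc belongs to the arm's proximal segment, which keeps every
arm segment at exactly ``L·W/10 = 70 cm²``; each platform sector facing an
arm loses the corresponding ~6 cm² sliver and stays within 15% of 70 cm².
The central platform piece has radius R/3, making all nine platform pieces
exactly one ninth of the disc before arm clipping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import numpy as np
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "MazeGeometry",
    "ArmEntryLine",
    "Zone",
    "MazeConfigError",
    "build_geometry",
    "render_mask",
    "classify_point",
    "classify_points",
    "distance_to_entry_line",
    "N_PLATFORM_PIECES",
    "SEGMENTS_PER_ARM",
]

N_PLATFORM_PIECES = 9
SEGMENTS_PER_ARM = 10
_N_SECTORS = N_PLATFORM_PIECES - 1  # annular sectors around the central disc
_ARC_STEPS = 256  # vertices used to discretize circular edges of zone polygons


class MazeConfigError(ValueError):
    """Raised for geometrically impossible maze configurations."""


@dataclass(frozen=True)
class ArmEntryLine:
    """Segment across the proximal end of one arm (the entry/exit test line)."""

    arm_index: int
    segment: tuple[tuple[float, float], tuple[float, float]]


@dataclass(frozen=True)
class Zone:
    """One piece of the statistical maze partition.

    ``kind`` is ``"platform-piece"`` (``segment_index`` 0 = central disc,
    1-8 = annular sectors) or ``"arm-segment"`` (``segment_index`` 0 =
    proximal ... 9 = distal; the distal segment doubles as the food zone).
    """

    zone_id: int
    kind: str
    arm_index: int | None
    segment_index: int
    polygon: _ShapelyPolygon

    @property
    def area_px2(self) -> float:
        return self.polygon.area


@dataclass(frozen=True)
class PointClass:
    """Result of classifying a point: region tag plus zone id (or None)."""

    region: str  # "platform" | "arm" | "outside"
    arm_index: int | None
    zone_id: int | None


@dataclass(eq=False)
class MazeGeometry:
    """Fully derived pixel-space maze model (build with :func:`build_geometry`)."""

    center: tuple[float, float] = (240.0, 240.0)
    n_arms: int = 8
    arm_angles: tuple[float, ...] = ()
    arm_length_cm: float = 70.0
    arm_width_cm: float = 10.0
    cm_per_px: float = 0.4
    platform_radius_cm: float = field(default=0.0)
    image_size: tuple[int, int] = (480, 480)  # (width, height)

    def __post_init__(self) -> None:
        if self.n_arms < 1:
            raise MazeConfigError("n_arms must be >= 1")
        if min(self.arm_length_cm, self.arm_width_cm, self.cm_per_px) <= 0:
            raise MazeConfigError("lengths and cm_per_px must be positive")
        if not self.arm_angles:
            step = 2 * math.pi / self.n_arms
            self.arm_angles = tuple(k * step for k in range(self.n_arms))
        if len(self.arm_angles) != self.n_arms:
            raise MazeConfigError("arm_angles length must equal n_arms")
        ang = np.sort(np.mod(self.arm_angles, 2 * math.pi))
        if self.n_arms > 1 and np.min(np.diff(np.concatenate([ang, [ang[0] + 2 * math.pi]]))) < 1e-9:
            raise MazeConfigError("arm angles must be pairwise distinct modulo 2π")
        if self.platform_radius_cm <= 0:
            # Platform sized so its 9 pieces are each ~70 cm² (≈ one arm segment).
            piece_cm2 = self.arm_length_cm * self.arm_width_cm / SEGMENTS_PER_ARM
            self.platform_radius_cm = math.sqrt(N_PLATFORM_PIECES * piece_cm2 / math.pi)
        if self.platform_radius_cm <= self.arm_width_cm / 2:
            raise MazeConfigError("platform too small for the arm width")
        # Angular clearance: adjacent arms must not overlap at the junction.
        half = math.atan2(self.arm_width_cm / 2, self.junction_offset_cm)
        if self.n_arms > 1:
            gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * math.pi]]))
            if np.min(gaps) <= 2 * half:
                raise MazeConfigError("arm width too large for the angular spacing")
        # Footprint must fit inside the working subimage.
        w, h = self.image_size
        reach = self.tip_radius_px + 0.5
        cx, cy = self.center
        if cx - reach < -0.5 or cy - reach < -0.5 or cx + reach > w - 0.5 or cy + reach > h - 0.5:
            raise MazeConfigError("maze footprint does not fit inside image_size")

    # -- derived scalar geometry -------------------------------------------------

    @property
    def arm_length_px(self) -> float:
        return self.arm_length_cm / self.cm_per_px

    @property
    def arm_width_px(self) -> float:
        return self.arm_width_cm / self.cm_per_px

    @property
    def platform_radius_px(self) -> float:
        return self.platform_radius_cm / self.cm_per_px

    @property
    def junction_offset_cm(self) -> float:
        """Distance from center to the arm's proximal edge (chord offset)."""
        return math.sqrt(self.platform_radius_cm**2 - (self.arm_width_cm / 2) ** 2)

    @property
    def junction_offset_px(self) -> float:
        return self.junction_offset_cm / self.cm_per_px

    @property
    def tip_radius_px(self) -> float:
        """Distance from center to the far corners of an arm."""
        tip = self.junction_offset_px + self.arm_length_px
        return math.hypot(tip, self.arm_width_px / 2)

    @property
    def n_zones(self) -> int:
        return self.n_arms * SEGMENTS_PER_ARM + N_PLATFORM_PIECES

    # -- derived structures --------------------------------------------------------

    @cached_property
    def entry_lines(self) -> tuple[ArmEntryLine, ...]:
        lines = []
        for k, theta in enumerate(self.arm_angles):
            c, s = math.cos(theta), math.sin(theta)
            u, hw = self.junction_offset_px, self.arm_width_px / 2
            cx, cy = self.center
            p1 = (cx + u * c - hw * s, cy + u * s + hw * c)
            p2 = (cx + u * c + hw * s, cy + u * s - hw * c)
            lines.append(ArmEntryLine(k, (p1, p2)))
        return tuple(lines)

    def _arm_rectangle(self, k: int) -> _ShapelyPolygon:
        return self._arm_segment_poly(k, 0, SEGMENTS_PER_ARM)

    def _arm_segment_poly(self, k: int, s0: int, s1: int) -> _ShapelyPolygon:
        theta = self.arm_angles[k]
        c, s = math.cos(theta), math.sin(theta)
        seg = self.arm_length_px / SEGMENTS_PER_ARM
        u0 = self.junction_offset_px + s0 * seg
        u1 = self.junction_offset_px + s1 * seg
        hw = self.arm_width_px / 2
        cx, cy = self.center
        corners = [(u0, -hw), (u1, -hw), (u1, hw), (u0, hw)]
        return _ShapelyPolygon(
            [(cx + u * c - v * s, cy + u * s + v * c) for u, v in corners]
        )

    def _disc(self, radius_px: float) -> _ShapelyPolygon:
        t = np.linspace(0, 2 * math.pi, _ARC_STEPS, endpoint=False)
        cx, cy = self.center
        return _ShapelyPolygon(
            np.column_stack([cx + radius_px * np.cos(t), cy + radius_px * np.sin(t)])
        )

    def _sector(self, a0: float, a1: float) -> _ShapelyPolygon:
        """Annular sector of the platform between angles a0 and a1."""
        r0 = self.platform_radius_px / 3
        r1 = self.platform_radius_px
        t = np.linspace(a0, a1, max(8, int(_ARC_STEPS * (a1 - a0) / (2 * math.pi))))
        cx, cy = self.center
        outer = np.column_stack([cx + r1 * np.cos(t), cy + r1 * np.sin(t)])
        inner = np.column_stack([cx + r0 * np.cos(t[::-1]), cy + r0 * np.sin(t[::-1])])
        return _ShapelyPolygon(np.vstack([outer, inner]))

    @cached_property
    def zones(self) -> tuple[Zone, ...]:
        arms_union = self._arm_rectangle(0)
        for k in range(1, self.n_arms):
            arms_union = arms_union.union(self._arm_rectangle(k))
        zones: list[Zone] = []
        # platform piece 0: central disc (never touches the arms for valid configs)
        center_poly = self._disc(self.platform_radius_px / 3).difference(arms_union)
        zones.append(Zone(0, "platform-piece", None, 0, center_poly))
        # platform pieces 1..8: annular sectors, clipped by the arm rectangles
        theta0 = self.arm_angles[0]
        step = 2 * math.pi / _N_SECTORS
        for i in range(_N_SECTORS):
            a0 = theta0 + (i - 0.5) * step
            poly = self._sector(a0, a0 + step).difference(arms_union)
            zones.append(Zone(1 + i, "platform-piece", None, 1 + i, poly))
        # arm segments: full rectangles (the disc overlap belongs to segment 0)
        for k in range(self.n_arms):
            for s in range(SEGMENTS_PER_ARM):
                poly = self._arm_segment_poly(k, s, s + 1)
                zones.append(
                    Zone(N_PLATFORM_PIECES + k * SEGMENTS_PER_ARM + s, "arm-segment", k, s, poly)
                )
        return tuple(zones)

    @cached_property
    def mask(self) -> np.ndarray:
        """Filled footprint raster: True inside platform ∪ arms."""
        region, _, _ = self._classify_grid()
        return region >= 0

    @cached_property
    def zone_map(self) -> np.ndarray:
        """Per-pixel zone id (−1 outside the footprint)."""
        _, _, zid = self._classify_grid()
        return zid

    def _classify_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        w, h = self.image_size
        xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        return _classify_arrays(self, xs.ravel(), ys.ravel(), reshape=(h, w))

    # -- convenience -------------------------------------------------------------

    def arm_frame(self, k: int, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates of points in arm k's frame: u along the axis from the
        center, v across the arm."""
        theta = self.arm_angles[k]
        dx = np.asarray(x, float) - self.center[0]
        dy = np.asarray(y, float) - self.center[1]
        c, s = math.cos(theta), math.sin(theta)
        return dx * c + dy * s, -dx * s + dy * c

    def food_zone_center(self, k: int, segment: int = SEGMENTS_PER_ARM - 1) -> tuple[float, float]:
        """Pixel center of a segment of arm k's axis (default the distal food zone)."""
        theta = self.arm_angles[k]
        seg = self.arm_length_px / SEGMENTS_PER_ARM
        u = self.junction_offset_px + (segment + 0.5) * seg
        return (self.center[0] + u * math.cos(theta), self.center[1] + u * math.sin(theta))


def _classify_arrays(
    geo: MazeGeometry, x: np.ndarray, y: np.ndarray, reshape: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized classification.

    Returns (region, arm, zone): region is −1 outside, 0 platform, 1 arm;
    arm is the arm index or −1; zone is the zone id or −1.  Points in the
    disc/arm overlap are classified as arm (matching the zone partition).
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    n = x.size
    region = np.full(n, -1, np.int8)
    arm = np.full(n, -1, np.int16)
    zone = np.full(n, -1, np.int32)

    seg_len = geo.arm_length_px / SEGMENTS_PER_ARM
    u0 = geo.junction_offset_px
    hw = geo.arm_width_px / 2
    for k in range(geo.n_arms):
        u, v = geo.arm_frame(k, x, y)
        hit = (u >= u0) & (u <= u0 + geo.arm_length_px) & (np.abs(v) <= hw) & (arm < 0)
        if hit.any():
            seg = np.minimum(((u[hit] - u0) / seg_len).astype(np.int32), SEGMENTS_PER_ARM - 1)
            arm[hit] = k
            region[hit] = 1
            zone[hit] = N_PLATFORM_PIECES + k * SEGMENTS_PER_ARM + seg

    dx = x - geo.center[0]
    dy = y - geo.center[1]
    r = np.hypot(dx, dy)
    plat = (r <= geo.platform_radius_px) & (arm < 0)
    region[plat] = 0
    inner = plat & (r <= geo.platform_radius_px / 3)
    zone[inner] = 0
    ring = plat & ~inner
    if ring.any():
        step = 2 * math.pi / _N_SECTORS
        ang = np.arctan2(dy[ring], dx[ring]) - geo.arm_angles[0]
        idx = np.floor(np.mod(ang + step / 2, 2 * math.pi) / step).astype(np.int32)
        zone[ring] = 1 + np.minimum(idx, _N_SECTORS - 1)

    if reshape is not None:
        return region.reshape(reshape), arm.reshape(reshape), zone.reshape(reshape)
    return region, arm, zone


def build_geometry(config: Mapping | None = None, **overrides) -> MazeGeometry:
    """Build a fully derived :class:`MazeGeometry` from a config mapping.

    Recognised keys (all optional): ``center``, ``n_arms``,
    ``arm_angles_deg`` (list), ``arm_length_cm``, ``arm_width_cm``,
    ``cm_per_px``, ``platform_radius_cm``, ``image_size``.
    """
    params = dict(config or {})
    params.update(overrides)
    if "arm_angles_deg" in params:
        params["arm_angles"] = tuple(math.radians(a) for a in params.pop("arm_angles_deg"))
    allowed = {
        "center",
        "n_arms",
        "arm_angles",
        "arm_length_cm",
        "arm_width_cm",
        "cm_per_px",
        "platform_radius_cm",
        "image_size",
    }
    unknown = set(params) - allowed
    if unknown:
        raise MazeConfigError(f"unknown geometry keys: {sorted(unknown)}")
    if "center" in params:
        params["center"] = tuple(float(v) for v in params["center"])
    if "image_size" in params:
        params["image_size"] = tuple(int(v) for v in params["image_size"])
    if "arm_angles" in params and params["arm_angles"] is not None:
        params["arm_angles"] = tuple(float(a) for a in params["arm_angles"])
    geo = MazeGeometry(**params)
    # touch derived structures so errors surface at build time
    geo.entry_lines
    return geo


def render_mask(geometry: MazeGeometry) -> np.ndarray:
    """Binary footprint raster of the maze (True = inside platform ∪ arms)."""
    return geometry.mask


def classify_point(geometry: MazeGeometry, p: tuple[float, float]) -> PointClass:
    """Classify a single point: region tag and zone id (None outside)."""
    x, y = float(p[0]), float(p[1])
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError("point coordinates must be finite")
    region, arm, zone = _classify_arrays(geometry, np.array([x]), np.array([y]))
    tag = {-1: "outside", 0: "platform", 1: "arm"}[int(region[0])]
    return PointClass(
        region=tag,
        arm_index=int(arm[0]) if arm[0] >= 0 else None,
        zone_id=int(zone[0]) if zone[0] >= 0 else None,
    )


def classify_points(
    geometry: MazeGeometry, x: Iterable[float], y: Iterable[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`classify_point`: returns (region, arm, zone) int arrays
    with −1 encoding outside/none."""
    return _classify_arrays(geometry, np.asarray(list(x), float), np.asarray(list(y), float))


def distance_to_entry_line(
    geometry: MazeGeometry, arm_index: int, p: tuple[float, float]
) -> float:
    """Euclidean distance (px) from a point to arm ``arm_index``'s entry segment."""
    if not 0 <= arm_index < geometry.n_arms:
        raise IndexError(f"arm_index {arm_index} out of range 0..{geometry.n_arms - 1}")
    (x1, y1), (x2, y2) = geometry.entry_lines[arm_index].segment
    px, py = float(p[0]), float(p[1])
    vx, vy = x2 - x1, y2 - y1
    t = ((px - x1) * vx + (py - y1) * vy) / (vx * vx + vy * vy)
    t = min(1.0, max(0.0, t))
    return math.hypot(px - (x1 + t * vx), py - (y1 + t * vy))
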