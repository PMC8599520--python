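"""Per-frame rat localization and sequence tracking.

The localization pipeline works on a single thresholded frame:

1. crop the working subimage, convert to grayscale, binarize (strict > 127);
   the binary image is conceptually duplicated (Image 1 / Image 2);
2. Image 1′ = Image 1 ∩ maze mask;  Image 1″ = opening(Image 1′, 5×5);
3. Image 2′ = opening(Image 2, 5×5);
4. C = Image 1″ ∩ Image 2′.  Components of C at least ``min_component_area``
   px with centroid inside the mask are the candidates.  One candidate → its
   centroid is the rat center.  Several → the largest wins (residual noise —
   droppings that survive the opening, the in-maze part of an intruder — is
   smaller than the rat).  None → fall back to the largest qualifying
   component of Image 1″; failing that the frame is flagged not-found and
   the previous position is carried forward by the sequence tracker.

The mask intersection discards everything outside the maze footprint and the
5×5 opening erases bright spots too small to contain the element, so small
droppings and out-of-maze clutter never reach the candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from . import imaging
from .geometry import MazeGeometry

__all__ = ["TargetPos", "TrackerParams", "locate_rat", "track_sequence", "detection_rate"]


@dataclass(frozen=True)
class TargetPos:
    """Estimated rat center for one sample tick."""

    t: float
    x: float
    y: float
    found: bool
    source: str  # single-outline | largest-in-maze | intersection-fallback | carried-forward | none


@dataclass
class TrackerParams:
    threshold: float = 127.0
    se_size: int = 5
    crop: tuple[int, int, int, int] | None = None  # (x0, y0, width, height)
    sample_period: float = 0.05
    min_component_area: int = 25

    def __post_init__(self) -> None:
        if self.sample_period <= 0:
            raise ValueError("sample_period must be positive")
        if self.se_size < 1 or self.se_size % 2 == 0:
            raise ValueError("se_size must be odd and >= 1")


def _prepare_binary(frame: np.ndarray, params: TrackerParams) -> np.ndarray:
    if params.crop is not None:
        x0, y0, w, h = params.crop
        frame = frame[y0 : y0 + h, x0 : x0 + w]
    if frame.ndim == 3:
        frame = imaging.rgb_to_gray(frame)
    return imaging.binarize(frame, params.threshold)


def _candidates(
    img: np.ndarray, mask: np.ndarray, min_area: int
) -> list[imaging.Component]:
    out = []
    for comp in imaging.extract_components(img):
        if comp.area < min_area:
            continue
        cx, cy = comp.centroid
        ix, iy = int(round(cx)), int(round(cy))
        comp.inside_maze = bool(
            0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1] and mask[iy, ix]
        )
        if comp.inside_maze:
            out.append(comp)
    return out


def locate_rat(
    frame: np.ndarray,
    geometry: MazeGeometry,
    params: TrackerParams | None = None,
    t: float = 0.0,
) -> TargetPos:
    """Locate the rat center in one frame (see the module pipeline description)."""
    params = params or TrackerParams()
    binary = _prepare_binary(frame, params)
    mask = geometry.mask
    if binary.shape != mask.shape:
        raise ValueError(
            f"frame (after crop) has shape {binary.shape}, geometry expects {mask.shape}"
        )
    se = imaging.square_element(params.se_size)
    image1pp = imaging.opening(imaging.intersect(binary, mask), se)
    image2p = imaging.opening(binary, se)
    combined = imaging.intersect(image1pp, image2p)

    cands = _candidates(combined, mask, params.min_component_area)
    if len(cands) == 1:
        cx, cy = cands[0].centroid
        return TargetPos(t, cx, cy, True, "single-outline")
    if len(cands) > 1:
        cx, cy = cands[0].centroid  # components come sorted largest-first
        return TargetPos(t, cx, cy, True, "largest-in-maze")
    fallback = _candidates(image1pp, mask, params.min_component_area)
    if fallback:
        cx, cy = fallback[0].centroid
        return TargetPos(t, cx, cy, True, "intersection-fallback")
    return TargetPos(t, float("nan"), float("nan"), False, "none")


def track_sequence(
    frames: Iterable[tuple[float, np.ndarray]],
    geometry: MazeGeometry,
    params: TrackerParams | None = None,
) -> list[TargetPos]:
    """Track a timestamped frame sequence, emitting one position per sample tick.

    ``frames`` yields ``(t_seconds, frame)`` in increasing time order.  Each
    output tick at ``k·sample_period`` uses the nearest frame at or before the
    tick.  Frames in which the rat is not found are carried forward from the
    last found position (flagged ``carried-forward``, found=False); leading
    not-found frames before any detection are emitted as not-found with NaN
    coordinates.
    """
    params = params or TrackerParams()
    it: Iterator[tuple[float, np.ndarray]] = iter(frames)
    cur = next(it, None)
    if cur is None:
        raise ValueError("empty frame source")

    out: list[TargetPos] = []
    last_found: TargetPos | None = None
    period = params.sample_period
    eps = 1e-9
    tick = 0
    while cur is not None:
        t_i, frame = cur
        nxt = next(it, None)
        # ticks served by this frame: those in [t_i, t_next) for interior
        # frames, or up to and including t_i for the final frame
        limit = (nxt[0] - eps) if nxt is not None else (t_i + eps)
        result: TargetPos | None = None  # located lazily, once per frame
        while tick * period <= limit:
            t_tick = tick * period
            tick += 1
            if t_tick < t_i - eps:
                # tick precedes the first frame: no evidence yet
                out.append(TargetPos(t_tick, float("nan"), float("nan"), False, "none"))
                continue
            if result is None:
                result = locate_rat(frame, geometry, params, t=t_i)
            if result.found:
                pos = TargetPos(t_tick, result.x, result.y, True, result.source)
                last_found = pos
            elif last_found is not None:
                pos = TargetPos(t_tick, last_found.x, last_found.y, False, "carried-forward")
            else:
                pos = TargetPos(t_tick, float("nan"), float("nan"), False, "none")
            out.append(pos)
        cur = nxt
    return out


def detection_rate(
    traj: Sequence[TargetPos],
    truth: np.ndarray,
    tol_px: float,
) -> float:
    """Percentage of samples located within ``tol_px`` of the true position.

    ``truth`` is an (n, 2) array of true (x, y) centers, one per sample. A
    sample counts as detected only if it was found (not carried forward) and
    its estimate lies within ``tol_px`` of the truth.
    """
    truth = np.asarray(truth, float)
    if len(traj) != len(truth):
        raise ValueError(f"length mismatch: {len(traj)} trajectory vs {len(truth)} truth")
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    hits = 0
    for pos, (tx, ty) in zip(traj, truth):
        if pos.found and np.hypot(pos.x - tx, pos.y - ty) <= tol_px:
            hits += 1
    return 100.0 * hits / len(traj)
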