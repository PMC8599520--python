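"""Pixel-level primitives: grayscale conversion, thresholding, binary morphology
and connected-component extraction.

All images are numpy arrays indexed ``[row, col]`` (y first); coordinates
reported to callers are ``(x, y)`` = ``(col, row)``, 0-based, origin at the
top-left.  Grayscale images are real-valued in ``[0, 255]`` (kept unrounded so
that thresholding is not perturbed by premature integer rounding); binary
images are boolean arrays.

The morphological operators follow the set-theoretic definitions

    erosion   A ⊖ B = { z | (B̂)_z ⊆ A }
    dilation  A ⊕ B = { z | (B̂)_z ∩ A ≠ ∅ }
    opening   A ∘ B = (A ⊖ B) ⊕ B

with B̂ the reflection of the structuring element B through its anchor and
pixels outside the image treated as background (0), which keeps opening
anti-extensive at the borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GRAY_WEIGHTS",
    "Component",
    "square_element",
    "rgb_to_gray",
    "binarize",
    "erode",
    "dilate",
    "opening",
    "intersect",
    "extract_components",
]

#: RGB -> luminance weights.  The G weight is 0.589 (the published value for
#: this pipeline), intentionally not the BT.601 0.587; the weights sum to
#: 1.002 so gray levels may marginally exceed 255.
GRAY_WEIGHTS = (0.299, 0.589, 0.114)

#: 8-connectivity structure for component labelling.
_CONN8 = np.ones((3, 3), bool)


def square_element(size: int = 5) -> np.ndarray:
    """All-ones square structuring element (default the 5×5 used for opening)."""
    if size < 1:
        raise ValueError("structuring element size must be >= 1")
    return np.ones((size, size), bool)


@dataclass
class Component:
    """One 8-connected white region of a binary image.

    Attributes
    ----------
    pixels : (n, 2) int array of (x, y) pixel coordinates.
    area : number of pixels.
    centroid : (x, y) arithmetic mean of the pixel coordinates (real-valued).
    inside_maze : whether the centroid lies inside the maze footprint;
        ``None`` until a tracker classifies it.
    """

    pixels: np.ndarray
    area: int
    centroid: tuple[float, float]
    inside_maze: bool | None = field(default=None)


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) image to real-valued grayscale.

    Gray(i, j) = 0.299·R + 0.589·G + 0.114·B, unrounded.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {rgb.shape}")
    r, g, b = GRAY_WEIGHTS
    return r * rgb[..., 0] + g * rgb[..., 1] + b * rgb[..., 2]


def binarize(gray: np.ndarray, threshold: float = 127) -> np.ndarray:
    """Threshold a grayscale image: 1 where gray > threshold (strict), else 0."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return np.asarray(gray) > threshold


def _prep(a: np.ndarray, se: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=bool)
    se = np.asarray(se, dtype=bool)
    if se.ndim != 2 or not se.any():
        raise ValueError("structuring element must be 2-D with at least one set pixel")
    return a, se


def _shift(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Translate a boolean raster by (dy, dx), filling with background."""
    if dy == 0 and dx == 0:
        return a
    out = np.zeros_like(a)
    h, w = a.shape
    ys, yd = (slice(0, h - dy), slice(dy, h)) if dy >= 0 else (slice(-dy, h), slice(0, h + dy))
    xs, xd = (slice(0, w - dx), slice(dx, w)) if dx >= 0 else (slice(-dx, w), slice(0, w + dx))
    out[yd, xd] = a[ys, xs]
    return out


def _anchor_shift(se: np.ndarray, anchor: tuple[int, int] | None) -> tuple[int, int]:
    # Work with a centered anchor and translate the result afterwards; the
    # translation vector is (center - anchor) in (dy, dx).
    cy, cx = se.shape[0] // 2, se.shape[1] // 2
    if anchor is None:
        return 0, 0
    ax, ay = anchor
    if not (0 <= ay < se.shape[0] and 0 <= ax < se.shape[1]):
        raise ValueError("anchor must lie inside the structuring element")
    return cy - ay, cx - ax


def erode(a: np.ndarray, se: np.ndarray, anchor: tuple[int, int] | None = None) -> np.ndarray:
    """Set-theoretic erosion A ⊖ B = { z | (B̂)_z ⊆ A }.

    Out-of-image pixels count as background, so containment fails at borders.
    ``anchor`` is the (x, y) reference pixel of the element (default: center).
    """
    a, se = _prep(a, se)
    dy, dx = _anchor_shift(se, anchor)
    out = ndimage.binary_erosion(a, structure=se[::-1, ::-1], border_value=0)
    return _shift(out, dy, dx)


def dilate(a: np.ndarray, se: np.ndarray, anchor: tuple[int, int] | None = None) -> np.ndarray:
    """Set-theoretic dilation A ⊕ B = { z | (B̂)_z ∩ A ≠ ∅ }."""
    a, se = _prep(a, se)
    dy, dx = _anchor_shift(se, anchor)
    out = ndimage.binary_dilation(a, structure=se)
    return _shift(out, dy, dx)


def opening(a: np.ndarray, se: np.ndarray, anchor: tuple[int, int] | None = None) -> np.ndarray:
    """Opening A ∘ B = (A ⊖ B) ⊕ B: removes bright structure too small to
    contain a translate of the element."""
    return dilate(erode(a, se, anchor), se, anchor)


def intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixelwise AND of two binary images of equal shape."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a & b


def extract_components(a: np.ndarray) -> list[Component]:
    """All maximal 8-connected white components of a binary image.

    Returned in descending area order; ties are broken by the smaller
    (y, x) of each component's topmost-leftmost pixel.
    """
    a = np.asarray(a, dtype=bool)
    labels, n = ndimage.label(a, structure=_CONN8)
    comps: list[Component] = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        # topmost-leftmost pixel: rows are emitted in order by nonzero
        top = (int(ys[0]), int(xs[np.argmin(xs[ys == ys[0]])]))
        comps.append(
            Component(
                pixels=np.column_stack([xs, ys]),
                area=int(ys.size),
                centroid=(float(xs.mean()), float(ys.mean())),
            )
        )
        comps[-1]._top = top  # type: ignore[attr-defined]
    comps.sort(key=lambda c: (-c.area, c._top))  # type: ignore[attr-defined]
    for c in comps:
        del c._top  # type: ignore[attr-defined]
    return comps
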