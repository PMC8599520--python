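import math

import numpy as np
import pytest

from ramtrack.geometry import build_geometry


@pytest.fixture(scope="session")
def geo():
    """Default 8-arm maze geometry (480x480 px working image, 0.4 cm/px)."""
    return build_geometry()


def draw_ellipse(frame, center, major, minor, theta=0.0, gray=200):
    """Fill a rotated ellipse into a grayscale frame (test fixture drawing)."""
    h, w = frame.shape
    cx, cy = center
    a, b = major / 2, minor / 2
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    u = (xs - cx) * math.cos(theta) + (ys - cy) * math.sin(theta)
    v = -(xs - cx) * math.sin(theta) + (ys - cy) * math.cos(theta)
    frame[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = gray
    return frame


@pytest.fixture
def blank_frame(geo):
    w, h = geo.image_size
    return np.full((h, w), 40, np.uint8)
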