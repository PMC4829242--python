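"""Polygon rasterisation over pixel centres.

Coordinates are 0-based with ``x`` the column index and ``y`` the row
index; a pixel belongs to a polygon when its centre ``(x, y)`` is inside
under the even-odd (crossing-number) rule. Fixing this convention is what
makes ROI means reproducible across implementations: image-analysis GUIs
each rasterise polygon selections slightly differently at the boundary.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import GeometryError, ValidationError

__all__ = ["polygon_mask", "polygon_pixel_count", "check_simple_polygon"]


def check_simple_polygon(vertices: np.ndarray) -> None:
    """Raise :class:`ValidationError` unless ``vertices`` form a simple
    (non-self-intersecting, non-degenerate) polygon with >= 3 vertices."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValidationError("a polygon needs >= 3 (x, y) vertices")
    if not np.all(np.isfinite(v)):
        raise ValidationError("polygon vertices must be finite")
    if not _ShapelyPolygon(v).is_valid:
        raise ValidationError("polygon is self-intersecting or degenerate")


def polygon_mask(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of shape ``(height, width)`` marking pixels whose
    centres lie inside the polygon (even-odd rule).

    Parameters
    ----------
    vertices
        ``(n, 2)`` array of ``(x, y)`` vertices, in order.
    shape
        ``(height, width)`` of the target raster.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValidationError("a polygon needs >= 3 (x, y) vertices")
    h, w = shape
    if h < 1 or w < 1:
        raise GeometryError("target raster must be at least 1x1")
    ys, xs = np.mgrid[0:h, 0:w]
    px = xs.ravel().astype(float)
    py = ys.ravel().astype(float)
    inside = np.zeros(px.shape, dtype=bool)
    x1, y1 = v[:, 0], v[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)
    for i in range(len(v)):
        if y1[i] == y2[i]:  # horizontal edge never crosses a horizontal ray
            continue
        crosses = (y1[i] > py) != (y2[i] > py)
        if not crosses.any():
            continue
        x_at = (x2[i] - x1[i]) * (py - y1[i]) / (y2[i] - y1[i]) + x1[i]
        inside ^= crosses & (px < x_at)
    return inside.reshape(h, w)


def polygon_pixel_count(vertices: np.ndarray, shape: tuple[int, int]) -> int:
    """Number of pixel centres inside the polygon."""
    return int(polygon_mask(vertices, shape).sum())
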