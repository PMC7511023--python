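"""Shared polygon geometry: boundary-inclusive point tests and pixel
rasterization.

One inclusion rule is used everywhere: a point (or pixel center) belongs
to a polygon iff the closed polygon intersects it — boundary counts as
inside. Grid points on a region border are therefore excluded from the
reference space (the conservative reading).
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon


def points_in_any_polygon(
    xs: np.ndarray, ys: np.ndarray, polygons: list[Polygon]
) -> np.ndarray:
    """Boolean mask: which (x, y) points fall inside (or on the boundary
    of) at least one polygon."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    hit = np.zeros(xs.shape, dtype=bool)
    for poly in polygons:
        if poly.is_empty:
            continue
        hit |= shapely.intersects_xy(poly, xs, ys)
    return hit


def rasterize_polygons(
    polygons: list[Polygon], shape: tuple[int, int]
) -> np.ndarray:
    """Pixel mask of the polygon union: pixel (r, c) is selected iff some
    polygon covers the point (x=c, y=r). Consistent with the point rule
    above, so a grid point is in the mask iff it is in a polygon."""
    out = np.zeros(shape, dtype=bool)
    h, w = shape
    for poly in polygons:
        if poly.is_empty:
            continue
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(int(np.floor(minx)), 0)
        c1 = min(int(np.ceil(maxx)) + 1, w)
        r0 = max(int(np.floor(miny)), 0)
        r1 = min(int(np.ceil(maxy)) + 1, h)
        if c0 >= c1 or r0 >= r1:
            continue
        cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        hit = shapely.intersects_xy(poly, cc.ravel(), rr.ravel())
        out[r0:r1, c0:c1] |= hit.reshape(rr.shape)
    return out
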