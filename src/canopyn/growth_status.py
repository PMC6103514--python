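"""Growth-status indicators from a segmented plant mask.

A nitrogen-starved sapling occupies its canopy envelope more sparsely than
a healthy one, so the ratio of plant pixels to the pixel count of a tight
enclosing shape carries nutritional signal.  Two shapes are used:

* ``GS_MCC = S_p / MCC_p`` — minimum circumscribed (enclosing) circle;
* ``GS_MER = S_p / MER_p`` — minimum-area enclosing rectangle.

``S_p`` is the foreground pixel count; ``MCC_p`` / ``MER_p`` are rasterized
counts of pixel centers inside the shape, so both ratios are dimensionless
and scale-free.  Geometry is computed on pixel centers in a 0-based frame
with x = column and y = row.

The enclosing circle is found with Welzl's randomized incremental
algorithm run on the convex hull of the foreground; the minimum-area
rectangle comes from the rotated-rectangle (hull-edge-aligned) solution.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "EnclosingCircle",
    "EnclosingRectangle",
    "GrowthStatus",
    "mask_points",
    "min_enclosing_circle",
    "min_enclosing_rectangle",
    "growth_status",
]

_EPS = 1e-7  # boundary tolerance for rasterized containment tests


@dataclass
class EnclosingCircle:
    """Smallest circle containing all foreground pixel centers."""

    center: tuple[float, float]
    radius: float
    pixel_count: int


@dataclass
class EnclosingRectangle:
    """Minimum-area (optionally axis-aligned) enclosing rectangle."""

    corners: np.ndarray          # (4, 2) in (x, y), consecutive order
    area: float                  # continuous area over pixel centers
    pixel_count: int


@dataclass
class GrowthStatus:
    s_p: int
    mer_p: int
    mcc_p: int
    gs_mer: float
    gs_mcc: float
    circle: EnclosingCircle
    rectangle: EnclosingRectangle


def mask_points(mask: np.ndarray) -> np.ndarray:
    """Foreground pixel centers of a mask as an (n, 2) array of (x, y)."""
    mask = np.asarray(mask).astype(bool)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("mask has no foreground pixels")
    return np.column_stack([xs, ys]).astype(np.float64)


# ---------------------------------------------------------------------------
# Minimum enclosing circle (Welzl, move-to-front variant)
# ---------------------------------------------------------------------------

def _circle_contains(c: tuple[float, float, float], p: np.ndarray) -> bool:
    cx, cy, r = c
    return np.hypot(p[0] - cx, p[1] - cy) <= r * (1 + 1e-12) + 1e-12


def _diameter_circle(p: np.ndarray, q: np.ndarray) -> tuple[float, float, float]:
    cx, cy = (p[0] + q[0]) / 2.0, (p[1] + q[1]) / 2.0
    r = max(np.hypot(p[0] - cx, p[1] - cy), np.hypot(q[0] - cx, q[1] - cy))
    return (cx, cy, r)


def _circumcircle(a, b, c) -> tuple[float, float, float] | None:
    d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
    if abs(d) < 1e-14:
        return None
    a2, b2, c2 = a[0] ** 2 + a[1] ** 2, b[0] ** 2 + b[1] ** 2, c[0] ** 2 + c[1] ** 2
    ux = (a2 * (b[1] - c[1]) + b2 * (c[1] - a[1]) + c2 * (a[1] - b[1])) / d
    uy = (a2 * (c[0] - b[0]) + b2 * (a[0] - c[0]) + c2 * (b[0] - a[0])) / d
    r = max(
        np.hypot(a[0] - ux, a[1] - uy),
        np.hypot(b[0] - ux, b[1] - uy),
        np.hypot(c[0] - ux, c[1] - uy),
    )
    return (ux, uy, r)


def _cross(ox, oy, ax, ay, bx, by) -> float:
    return (ax - ox) * (by - oy) - (ay - oy) * (bx - ox)


def _mec_two_fixed(points: np.ndarray, p: np.ndarray, q: np.ndarray):
    """Smallest circle through p and q containing ``points``."""
    circ = _diameter_circle(p, q)
    left = None
    right = None
    for r in points:
        if _circle_contains(circ, r):
            continue
        cross = _cross(p[0], p[1], q[0], q[1], r[0], r[1])
        c = _circumcircle(p, q, r)
        if c is None:
            continue
        if cross > 0 and (
            left is None
            or _cross(p[0], p[1], q[0], q[1], c[0], c[1])
            > _cross(p[0], p[1], q[0], q[1], left[0], left[1])
        ):
            left = c
        elif cross < 0 and (
            right is None
            or _cross(p[0], p[1], q[0], q[1], c[0], c[1])
            < _cross(p[0], p[1], q[0], q[1], right[0], right[1])
        ):
            right = c
    if left is None and right is None:
        return circ
    if left is None:
        return right
    if right is None:
        return left
    return left if left[2] <= right[2] else right


def _mec_one_fixed(points: np.ndarray, p: np.ndarray):
    c = (float(p[0]), float(p[1]), 0.0)
    for j in range(len(points)):
        q = points[j]
        if not _circle_contains(c, q):
            if c[2] == 0.0:
                c = _diameter_circle(p, q)
            else:
                c = _mec_two_fixed(points[: j + 1], p, q)
    return c


def _welzl(points: np.ndarray) -> tuple[float, float, float]:
    rng = np.random.default_rng(0x5EED)  # internal shuffle only; output is unique
    pts = points[rng.permutation(len(points))]
    c = None
    for i in range(len(pts)):
        p = pts[i]
        if c is None or not _circle_contains(c, p):
            c = _mec_one_fixed(pts[: i + 1], p)
    return c


def _hull_points(points: np.ndarray) -> np.ndarray:
    """Convex-hull vertices, falling back to the full set when degenerate."""
    points = np.unique(points, axis=0)
    if len(points) <= 3:
        return points
    try:
        hull = ConvexHull(points)
    except QhullError:
        return points  # collinear or otherwise degenerate
    return points[hull.vertices]


def min_enclosing_circle(mask: np.ndarray) -> EnclosingCircle:
    """Minimum circumscribed circle of the foreground, with MCC_p count."""
    mask = np.asarray(mask).astype(bool)
    pts = mask_points(mask)
    hull = _hull_points(pts)
    cx, cy, r = _welzl(hull)
    count = _circle_pixel_count(mask.shape, cx, cy, r)
    s_p = int(mask.sum())
    return EnclosingCircle((float(cx), float(cy)), float(r), max(count, s_p))


def _circle_pixel_count(shape, cx: float, cy: float, r: float) -> int:
    h, w = shape
    x0 = max(0, int(np.floor(cx - r - _EPS)))
    x1 = min(w - 1, int(np.ceil(cx + r + _EPS)))
    y0 = max(0, int(np.floor(cy - r - _EPS)))
    y1 = min(h - 1, int(np.ceil(cy + r + _EPS)))
    xs = np.arange(x0, x1 + 1, dtype=np.float64)
    ys = np.arange(y0, y1 + 1, dtype=np.float64)
    dx2 = (xs - cx) ** 2
    dy2 = (ys - cy) ** 2
    inside = dy2[:, None] + dx2[None, :] <= (r + _EPS) ** 2
    return int(inside.sum())


# ---------------------------------------------------------------------------
# Minimum enclosing rectangle
# ---------------------------------------------------------------------------

def min_enclosing_rectangle(
    mask: np.ndarray, rotated: bool = True
) -> EnclosingRectangle:
    """Minimum-area enclosing rectangle of the foreground, with MER_p count.

    By default the rectangle may be arbitrarily oriented (minimum-area
    rotated rectangle over the convex hull); ``rotated=False`` gives the
    axis-aligned bounding box instead.
    """
    mask = np.asarray(mask).astype(bool)
    pts = mask_points(mask)
    s_p = int(mask.sum())

    if not rotated:
        x0, y0 = pts.min(axis=0)
        x1, y1 = pts.max(axis=0)
        corners = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], float)
    else:
        geom = shapely.MultiPoint(pts)
        env = shapely.oriented_envelope(geom)
        if env.geom_type == "Polygon":
            corners = np.asarray(env.exterior.coords[:4], dtype=np.float64)
        elif env.geom_type == "LineString":
            a, b = np.asarray(env.coords[0]), np.asarray(env.coords[-1])
            corners = np.array([a, b, b, a], dtype=np.float64)
        else:  # Point
            p = np.asarray(env.coords[0], dtype=np.float64)
            corners = np.tile(p, (4, 1))

    area = _polygon_area(corners)
    count = _rect_pixel_count(mask.shape, corners)
    return EnclosingRectangle(corners, float(area), max(count, s_p))


def _polygon_area(corners: np.ndarray) -> float:
    x, y = corners[:, 0], corners[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _rect_pixel_count(shape, corners: np.ndarray) -> int:
    """Pixel centers inside or on a (possibly degenerate) rectangle."""
    h, w = shape
    c0 = corners[0]
    u = corners[1] - c0
    v = corners[3] - c0
    lu, lv = np.hypot(*u), np.hypot(*v)

    x0 = max(0, int(np.floor(corners[:, 0].min() - _EPS)))
    x1 = min(w - 1, int(np.ceil(corners[:, 0].max() + _EPS)))
    y0 = max(0, int(np.floor(corners[:, 1].min() - _EPS)))
    y1 = min(h - 1, int(np.ceil(corners[:, 1].max() + _EPS)))
    if x1 < x0 or y1 < y0:
        return 0
    xs, ys = np.meshgrid(
        np.arange(x0, x1 + 1, dtype=np.float64),
        np.arange(y0, y1 + 1, dtype=np.float64),
    )
    px = xs - c0[0]
    py = ys - c0[1]

    def _along(axis, length):
        ux, uy = axis[0] / length, axis[1] / length
        s = px * ux + py * uy  # signed distance along the unit axis
        return (s >= -_EPS) & (s <= length + _EPS)

    if lu < _EPS and lv < _EPS:  # single point
        return int(((np.abs(px) <= _EPS) & (np.abs(py) <= _EPS)).sum())
    if lu < _EPS or lv < _EPS:   # collinear foreground: a segment
        axis, length = (v, lv) if lu < _EPS else (u, lu)
        ux, uy = axis[0] / length, axis[1] / length
        perp = np.abs(px * uy - py * ux)
        return int((_along(axis, length) & (perp <= _EPS)).sum())
    return int((_along(u, lu) & _along(v, lv)).sum())


def growth_status(
    mask: np.ndarray, rotated_rectangle: bool = True, clamp: bool = True
) -> GrowthStatus:
    """Compute S_p, MER_p, MCC_p and the two growth-status ratios.

    Ratios can exceed 1 by at most boundary-pixel effects; with ``clamp``
    (the default) they are clamped into (0, 1].
    """
    mask = np.asarray(mask).astype(bool)
    circle = min_enclosing_circle(mask)
    rect = min_enclosing_rectangle(mask, rotated=rotated_rectangle)
    s_p = int(mask.sum())
    gs_mer = s_p / rect.pixel_count
    gs_mcc = s_p / circle.pixel_count
    if clamp:
        gs_mer = min(gs_mer, 1.0)
        gs_mcc = min(gs_mcc, 1.0)
    return GrowthStatus(
        s_p=s_p, mer_p=rect.pixel_count, mcc_p=circle.pixel_count,
        gs_mer=gs_mer, gs_mcc=gs_mcc, circle=circle, rectangle=rect,
    )
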