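"""Optic-disc geometry: minimum enclosing circle and the concentric analysis ring.

All vessel statistics are computed inside an annular region of interest (ROI)
anchored on the optic disc (OD): the smallest circle containing every OD
foreground pixel is fitted, and the ring spanning 2x to 4x its radius around
its center is the sole analysis region.  Pixel coordinates are 0-based, x
rightward, y downward, with pixel centers at integer positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = ["Circle", "RoiRing", "min_enclosing_circle", "build_roi", "mask_to_roi"]

_EPS = 1e-9


@dataclass(frozen=True)
class Circle:
    """A circle with real-valued center (x, y) and radius, in pixels."""

    center: tuple[float, float]
    radius: float

    def contains(self, x: float, y: float, tol: float = 1e-6) -> bool:
        dx = x - self.center[0]
        dy = y - self.center[1]
        return dx * dx + dy * dy <= (self.radius + tol) ** 2


@dataclass(frozen=True)
class RoiRing:
    """Concentric annulus [r_inner, r_outer) around the OD center.

    ``pixel_count`` is the number of in-image pixel centers whose distance d
    from the center satisfies r_inner <= d < r_outer (half-open, so every
    pixel belongs to exactly one of the disc-adjacent / ring / peripheral
    zones).
    """

    center: tuple[float, float]
    r_inner: float
    r_outer: float
    pixel_count: int


def _circle_from_2(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    c = (p + q) / 2.0
    return c, float(np.hypot(*(p - c)))


def _circle_from_3(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, float] | None:
    ax, ay = p
    bx, by = q
    cx, cy = r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-14:
        return None  # collinear
    ux = ((ax * ax + ay * ay) * (by - cy) + (bx * bx + by * by) * (cy - ay)
          + (cx * cx + cy * cy) * (ay - by)) / d
    uy = ((ax * ax + ay * ay) * (cx - bx) + (bx * bx + by * by) * (ax - cx)
          + (cx * cx + cy * cy) * (bx - ax)) / d
    c = np.array([ux, uy])
    return c, float(np.hypot(*(p - c)))


def _in_circle(c: np.ndarray, r: float, p: np.ndarray) -> bool:
    return float(np.hypot(*(p - c))) <= r + _EPS


def _mec_with_two(points: np.ndarray, p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    c, r = _circle_from_2(p, q)
    for s in points:
        if not _in_circle(c, r, s):
            res = _circle_from_3(p, q, s)
            if res is not None:
                c, r = res
    return c, r


def _mec_with_one(points: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, float]:
    c, r = p.astype(float), 0.0
    for i, q in enumerate(points):
        if not _in_circle(c, r, q):
            c, r = _mec_with_two(points[: i + 1], p, q)
    return c, r


def min_enclosing_circle(points) -> Circle:
    """Exact minimum enclosing circle of a 2D point set.

    Move-to-front style incremental construction (Welzl) run on the convex
    hull of the input, with points in sorted order so the result is
    deterministic and independent of input ordering.

    Parameters
    ----------
    points : array-like of shape (n, 2)
        (x, y) coordinates; at least one point.
    """
    pts = np.asarray(list(points) if not isinstance(points, np.ndarray) else points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("min_enclosing_circle requires a non-empty (n, 2) point set")
    pts = np.unique(pts, axis=0)  # sorts lexicographically -> order-independent
    if pts.shape[0] == 1:
        return Circle((float(pts[0, 0]), float(pts[0, 1])), 0.0)
    if pts.shape[0] > 4:
        try:
            hull = ConvexHull(pts)
            pts = np.unique(pts[hull.vertices], axis=0)
        except QhullError:
            pass  # degenerate (collinear) inputs: fall through with all points
    c, r = pts[0].astype(float), 0.0
    for i in range(1, pts.shape[0]):
        if not _in_circle(c, r, pts[i]):
            c, r = _mec_with_one(pts[: i + 1], pts[i])
    return Circle((float(c[0]), float(c[1])), float(r))


def mec_of_mask(mask: np.ndarray) -> Circle:
    """Minimum enclosing circle of a binary mask's foreground pixel centers."""
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    if xs.size == 0:
        raise ValueError("mask has no foreground pixels")
    return min_enclosing_circle(np.column_stack([xs, ys]))


def ring_pixel_count(center: tuple[float, float], r_inner: float, r_outer: float,
                     width: int, height: int) -> int:
    """Count pixel centers inside the half-open annulus, clipped to the image."""
    ys, xs = np.ogrid[0:height, 0:width]
    d2 = (xs - center[0]) ** 2 + (ys - center[1]) ** 2
    return int(np.count_nonzero((d2 >= r_inner ** 2) & (d2 < r_outer ** 2)))


def build_roi(od_circle: Circle, width: int, height: int,
              inner_factor: float = 2.0, outer_factor: float = 4.0) -> RoiRing:
    """Construct the analysis annulus spanning 2x-4x the OD circle radius.

    Raises
    ------
    ValueError
        If the OD circle is degenerate (radius 0) or the ring lies entirely
        outside the image, in which case the frame is unanalyzable.
    """
    if od_circle.radius <= 0:
        raise ValueError("degenerate optic disc: minimum enclosing circle radius is 0")
    r_in = inner_factor * od_circle.radius
    r_out = outer_factor * od_circle.radius
    n = ring_pixel_count(od_circle.center, r_in, r_out, width, height)
    if n == 0:
        raise ValueError("ROI ring lies entirely outside the image bounds")
    return RoiRing(od_circle.center, r_in, r_out, n)


def mask_to_roi(mask: np.ndarray, roi: RoiRing) -> np.ndarray:
    """Restrict a binary mask to the ROI ring (inner-inclusive, outer-exclusive)."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    ys, xs = np.ogrid[0:h, 0:w]
    d2 = (xs - roi.center[0]) ** 2 + (ys - roi.center[1]) ** 2
    return m & (d2 >= roi.r_inner ** 2) & (d2 < roi.r_outer ** 2)
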