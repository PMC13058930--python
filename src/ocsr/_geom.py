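"""Small 2D geometry helpers shared by the detection modules.

Points are (x, y) tuples or (N, 2) float arrays; angles are degrees.
Line *angles* live in [0, 180) (undirected orientation).
"""

from __future__ import annotations

import math

import numpy as np

Point = tuple[float, float]


def angle_of(p1: Point, p2: Point) -> float:
    """Undirected orientation of the segment p1->p2, in [0, 180) degrees."""
    a = math.degrees(math.atan2(p2[1] - p1[1], p2[0] - p1[0])) % 180.0
    return a


def angle_diff(a: float, b: float) -> float:
    """Distance between two undirected orientations, in [0, 90] degrees."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def dist(p1: Point, p2: Point) -> float:
    return math.hypot(p1[0] - p2[0], p1[1] - p2[1])


def point_line_distance(p: Point, a: Point, b: Point) -> float:
    """Perpendicular distance from p to the infinite line through a, b."""
    ax, ay = a
    bx, by = b
    dx, dy = bx - ax, by - ay
    n = math.hypot(dx, dy)
    if n == 0:
        return dist(p, a)
    return abs(dy * (p[0] - ax) - dx * (p[1] - ay)) / n


def project_onto(p: Point, origin: Point, direction: Point) -> float:
    """Scalar projection of p onto the unit `direction` anchored at origin."""
    return (p[0] - origin[0]) * direction[0] + (p[1] - origin[1]) * direction[1]


def unit_direction(a: Point, b: Point) -> Point:
    dx, dy = b[0] - a[0], b[1] - a[1]
    n = math.hypot(dx, dy)
    if n == 0:
        return (1.0, 0.0)
    return (dx / n, dy / n)


def segment_intersection(a1: Point, a2: Point, b1: Point, b2: Point):
    """Intersection of segments a and b.

    Returns (t, u, point) with parametric positions t on a and u on b, or
    None when the segments are parallel.
    """
    x1, y1 = a1
    x2, y2 = a2
    x3, y3 = b1
    x4, y4 = b2
    den = (x2 - x1) * (y4 - y3) - (y2 - y1) * (x4 - x3)
    if abs(den) < 1e-12:
        return None
    t = ((x3 - x1) * (y4 - y3) - (y3 - y1) * (x4 - x3)) / den
    u = ((x3 - x1) * (y2 - y1) - (y3 - y1) * (x2 - x1)) / den
    pt = (x1 + t * (x2 - x1), y1 + t * (y2 - y1))
    return t, u, pt


def point_segment_distance(p: Point, a: Point, b: Point) -> float:
    """Distance from p to the (finite) segment ab."""
    ax, ay = a
    bx, by = b
    dx, dy = bx - ax, by - ay
    n2 = dx * dx + dy * dy
    if n2 == 0:
        return dist(p, a)
    t = ((p[0] - ax) * dx + (p[1] - ay) * dy) / n2
    t = max(0.0, min(1.0, t))
    return dist(p, (ax + t * dx, ay + t * dy))


def oriented_extent(pixels: np.ndarray) -> tuple[float, float, float, Point]:
    """PCA-oriented bounding extents of a pixel cloud.

    Returns (length, width, axis_angle_deg, center) where length >= width and
    axis_angle is the orientation of the long axis in [0, 180).  A pixel is
    treated as a unit square, so extents include +1.
    """
    pts = np.asarray(pixels, dtype=float)
    c = pts.mean(axis=0)
    centered = pts - c
    if len(pts) == 1:
        return 1.0, 1.0, 0.0, (float(c[0]), float(c[1]))
    cov = centered.T @ centered / len(pts)
    vals, vecs = np.linalg.eigh(cov)
    major = vecs[:, int(np.argmax(vals))]
    minor = np.array([-major[1], major[0]])
    along = centered @ major
    across = centered @ minor
    length = float(along.max() - along.min()) + 1.0
    width = float(across.max() - across.min()) + 1.0
    ang = math.degrees(math.atan2(major[1], major[0])) % 180.0
    if width > length:
        length, width = width, length
        ang = (ang + 90.0) % 180.0
    return length, width, ang, (float(c[0]), float(c[1]))


def fit_line_residual(points: np.ndarray) -> float:
    """Variance of perpendicular residuals of points about their PCA line."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    c = pts.mean(axis=0)
    centered = pts - c
    cov = centered.T @ centered / len(pts)
    vals = np.linalg.eigvalsh(cov)
    return float(vals[0])
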