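"""Turn detected lines, shapes and circles into typed chemical bonds.

Processing order matters and is fixed: parallel line groups become multibonds,
long crossing lines are split at interior intersections, collinear
single-into-multibond runs are split, then the style detectors run
(solid wedge, dashed, wavy) and finally circle-bearing rings are flagged
aromatic.  Every operation is pure: it returns a new bond list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.cluster.hierarchy import DisjointSet
from scipy.spatial import cKDTree

from . import _geom
from .fmlines import DetectedLine
from .raster import BinaryImage, Circle, Shape, detect_circles, measure_arc

log = logging.getLogger(__name__)

Point = tuple[float, float]


class BondStyle(str, Enum):
    SOLID = "solid_line"
    SOLID_WEDGE = "solid_wedge"
    DASHED_LINE = "dashed_line"
    DASHED_WEDGE = "dashed_wedge"
    WAVY = "wavy"
    AROMATIC = "aromatic"


@dataclass
class Bond:
    """A typed bond hypothesis with two ending points.

    ``coords`` holds the skeleton-level source pixels; ``segments`` the line
    segments to sample for the ink-coverage existence rule (one per member
    line of a multibond).
    """

    style: BondStyle
    degree: int
    end1: Point
    end2: Point
    coords: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    segments: tuple[tuple[Point, Point], ...] = ()

    def __post_init__(self):
        if not self.segments:
            self.segments = ((self.end1, self.end2),)

    @property
    def length(self) -> float:
        return _geom.dist(self.end1, self.end2)

    @property
    def center(self) -> Point:
        return ((self.end1[0] + self.end2[0]) / 2.0, (self.end1[1] + self.end2[1]) / 2.0)

    @property
    def angle(self) -> float:
        return _geom.angle_of(self.end1, self.end2)


def bond_from_line(line: DetectedLine) -> Bond:
    return Bond(
        style=BondStyle.SOLID,
        degree=1,
        end1=(float(line.end1[0]), float(line.end1[1])),
        end2=(float(line.end2[0]), float(line.end2[1])),
        coords=line.pixels,
    )


def median_line_length(lines: list[DetectedLine]) -> float:
    """Robust median bond-line length.

    Dash strokes, squiggle pieces and letter strokes are legitimate short
    detections and may outnumber true bond lines, so a plain median (or even
    a fixed percentile) collapses.  Bond lines form the *upper* length mode:
    starting from the 95th-percentile length, iterate a trimmed median over
    lines at least 55% of the current estimate.
    """
    if not lines:
        return 0.0
    lengths = np.array([l.length for l in lines])
    # seed from the upper end: tiny molecules may have more letter strokes
    # than bond lines, which would dominate any fixed percentile
    est = max(float(np.percentile(lengths, 95)), 0.75 * float(lengths.max()))
    for _ in range(3):
        core = lengths[lengths >= 0.55 * est]
        if len(core) == 0:
            break
        new = float(np.median(core))
        if abs(new - est) < 1e-9:
            break
        est = new
    return est


# ---------------------------------------------------------------------------
# multibond grouping and splitting
# ---------------------------------------------------------------------------


def _overlap_ratio(a: DetectedLine | Bond, b: DetectedLine | Bond) -> float:
    """Shared extent along the mean direction, relative to the shorter line."""
    ang = math.radians(a.angle)
    u = (math.cos(ang), math.sin(ang))
    ia = sorted([_geom.project_onto(a.end1, (0, 0), u), _geom.project_onto(a.end2, (0, 0), u)])
    ib = sorted([_geom.project_onto(b.end1, (0, 0), u), _geom.project_onto(b.end2, (0, 0), u)])
    inter = min(ia[1], ib[1]) - max(ia[0], ib[0])
    shorter = min(ia[1] - ia[0], ib[1] - ib[0])
    if shorter <= 0:
        return 0.0
    return max(0.0, inter) / shorter


def group_multibonds(
    lines: list[DetectedLine],
    lmed: float,
    angle_tol: float = 5.0,
    lateral_frac: float = 0.35,
    min_len_ratio: float = 0.6,
    min_overlap: float = 0.6,
    min_member_frac: float = 0.4,
) -> list[Bond]:
    """Group 2–3 parallel, close, similar-length lines into one multibond.

    Lines shorter than ``min_member_frac * lmed`` (dash strokes and other
    sub-bond detections) never join a group and pass through as degree-1
    bonds.  Multibond endings are the per-side means of member endings.
    """
    n = len(lines)
    eligible = [i for i in range(n) if lines[i].length >= min_member_frac * lmed]
    ds = DisjointSet(range(n))
    for ii, i in enumerate(eligible):
        for j in eligible[ii + 1 :]:
            a, b = lines[i], lines[j]
            if _geom.angle_diff(a.angle, b.angle) > angle_tol:
                continue
            lat = min(
                _geom.point_line_distance(a.center, b.end1, b.end2),
                _geom.point_line_distance(b.center, a.end1, a.end2),
            )
            if lat > lateral_frac * lmed or lat < 1.0:
                continue
            if min(a.length, b.length) / max(a.length, b.length) < min_len_ratio:
                continue
            if _overlap_ratio(a, b) < min_overlap:
                continue
            ds.merge(i, j)
    bonds = []
    for group in sorted(ds.subsets(), key=lambda g: min(g)):
        members = [lines[i] for i in sorted(group)]
        if len(members) == 1:
            bonds.append(bond_from_line(members[0]))
            continue
        if len(members) > 3:
            log.warning("multibond group of %d parallel lines; keeping 3 longest", len(members))
            members.sort(key=lambda l: -l.length)
            extras, members = members[3:], members[:3]
            bonds.extend(bond_from_line(l) for l in extras)
            members.sort(key=lambda l: (l.end1, l.end2))
        bonds.append(_merge_parallel(members))
    bonds.sort(key=lambda b: (b.end1, b.end2, b.degree))
    return bonds


def _merge_parallel(members: list[DetectedLine | Bond]) -> Bond:
    """Combine parallel lines into one bond: degree = count, per-side mean ends."""
    ref = max(members, key=lambda m: _geom.dist(m.end1, m.end2))
    u = _geom.unit_direction(ref.end1, ref.end2)
    side1, side2 = [], []
    for m in members:
        p1, p2 = m.end1, m.end2
        if _geom.project_onto(p1, ref.end1, u) > _geom.project_onto(p2, ref.end1, u):
            p1, p2 = p2, p1
        side1.append(p1)
        side2.append(p2)
    e1 = (float(np.mean([p[0] for p in side1])), float(np.mean([p[1] for p in side1])))
    e2 = (float(np.mean([p[0] for p in side2])), float(np.mean([p[1] for p in side2])))
    coords_list = [
        c
        for c in (m.pixels if isinstance(m, DetectedLine) else m.coords for m in members)
        if len(c)
    ]
    coords = (
        np.unique(np.vstack(coords_list), axis=0) if coords_list else np.empty((0, 2), int)
    )
    degree = sum(getattr(m, "degree", 1) for m in members)
    segs = []
    for m in members:
        if isinstance(m, Bond):
            segs.extend(m.segments)
        else:
            segs.append(((float(m.end1[0]), float(m.end1[1])), (float(m.end2[0]), float(m.end2[1]))))
    if degree > 3:
        log.warning("merged bond degree %d capped at 3", degree)
        degree = 3
    return Bond(style=BondStyle.SOLID, degree=degree, end1=e1, end2=e2,
                coords=coords, segments=tuple(segs))


def split_at_intersections(bonds: list[Bond], lmed: float) -> list[Bond]:
    """Split two long solid lines crossing strictly inside both.

    An interior crossing (at least ``max(4, 0.1*length)`` px from every
    endpoint on both segments) indicates an implicit carbon; each segment is
    replaced by two bonds meeting at the intersection point.
    """
    bonds = list(bonds)
    changed = True
    guard = 0
    while changed and guard < 50:
        changed = False
        guard += 1
        for i in range(len(bonds)):
            for j in range(i + 1, len(bonds)):
                a, b = bonds[i], bonds[j]
                if a.style != BondStyle.SOLID or b.style != BondStyle.SOLID:
                    continue
                hit = _geom.segment_intersection(a.end1, a.end2, b.end1, b.end2)
                if hit is None:
                    continue
                t, v, pt = hit
                min_a = max(4.0, 0.1 * a.length) / max(a.length, 1e-9)
                min_b = max(4.0, 0.1 * b.length) / max(b.length, 1e-9)
                if not (min_a < t < 1 - min_a and min_b < v < 1 - min_b):
                    continue
                new = [
                    _sub_bond(a, a.end1, pt),
                    _sub_bond(a, pt, a.end2),
                    _sub_bond(b, b.end1, pt),
                    _sub_bond(b, pt, b.end2),
                ]
                bonds = [x for k, x in enumerate(bonds) if k not in (i, j)] + new
                changed = True
                break
            if changed:
                break
    bonds.sort(key=lambda b: (b.end1, b.end2, b.degree))
    return bonds


def _sub_bond(src: Bond, p1: Point, p2: Point) -> Bond:
    u = _geom.unit_direction(p1, p2)
    mid = ((p1[0] + p2[0]) / 2, (p1[1] + p2[1]) / 2)
    if len(src.coords):
        proj = (src.coords[:, 0] - mid[0]) * u[0] + (src.coords[:, 1] - mid[1]) * u[1]
        half = _geom.dist(p1, p2) / 2 + 1.5
        coords = src.coords[np.abs(proj) <= half]
    else:
        coords = src.coords
    return Bond(style=src.style, degree=src.degree, end1=p1, end2=p2,
                coords=coords, segments=((p1, p2),))


def split_collinear(
    bonds: list[Bond],
    lmed: float,
    angle_tol: float = 5.0,
    lateral_frac: float = 0.35,
    min_overhang_frac: float = 0.3,
) -> list[Bond]:
    """Split a long line where a collinear-running parallel short bond ends.

    Handles a single bond continuing straight into a double/triple bond: the
    long center line is split at the projections of the short parallel bond's
    endings; the covered piece joins the short bond (degree + 1) and the
    overhangs stay degree-1 bonds.
    """
    bonds = list(bonds)
    changed = True
    guard = 0
    min_overhang = min_overhang_frac * lmed
    while changed and guard < 50:
        changed = False
        guard += 1
        for i in range(len(bonds)):
            for j in range(len(bonds)):
                if i == j:
                    continue
                lng, sht = bonds[i], bonds[j]
                if lng.style != BondStyle.SOLID or sht.style != BondStyle.SOLID:
                    continue
                if lng.degree != 1 or lng.length <= sht.length:
                    continue
                if _geom.angle_diff(lng.angle, sht.angle) > angle_tol:
                    continue
                lat = _geom.point_line_distance(sht.center, lng.end1, lng.end2)
                if not (1.0 <= lat <= lateral_frac * lmed):
                    continue
                u = _geom.unit_direction(lng.end1, lng.end2)
                s1 = _geom.project_onto(sht.end1, lng.end1, u)
                s2 = _geom.project_onto(sht.end2, lng.end1, u)
                lo, hi = sorted((s1, s2))
                L = lng.length
                if lo < -2 or hi > L + 2:
                    continue  # short bond not covered by the long one
                over_left = lo
                over_right = L - hi
                if max(over_left, over_right) < min_overhang:
                    continue  # same extent: multibond grouping territory
                pieces = []
                cuts = []
                if over_left >= min_overhang:
                    cuts.append(lo)
                if over_right >= min_overhang:
                    cuts.append(hi)
                pos = [0.0] + cuts + [L]
                for a, b in zip(pos[:-1], pos[1:]):
                    if b - a < 1.0:
                        continue
                    p1 = (lng.end1[0] + u[0] * a, lng.end1[1] + u[1] * a)
                    p2 = (lng.end1[0] + u[0] * b, lng.end1[1] + u[1] * b)
                    pieces.append(_sub_bond(lng, p1, p2))
                matched = min(
                    pieces,
                    key=lambda p: _geom.dist(p.center, sht.center),
                )
                merged = _merge_parallel([matched, sht])
                merged = replace(merged, degree=min(3, sht.degree + 1))
                new = [p for p in pieces if p is not matched] + [merged]
                bonds = [x for k, x in enumerate(bonds) if k not in (i, j)] + new
                changed = True
                break
            if changed:
                break
    bonds.sort(key=lambda b: (b.end1, b.end2, b.degree))
    return bonds


# ---------------------------------------------------------------------------
# style detectors
# ---------------------------------------------------------------------------


def _stroke_width(pix: np.ndarray, pt: Point, normal: Point, max_width: int = 40) -> int:
    """Perpendicular ink run length through ``pt`` along ``normal``."""
    h, w = pix.shape

    def ink(d: float) -> bool:
        x = int(round(pt[0] + d * normal[0]))
        y = int(round(pt[1] + d * normal[1]))
        return 0 <= x < w and 0 <= y < h and bool(pix[y, x])

    anchor = None
    for d0 in (0, 1, -1, 2, -2):
        if ink(d0):
            anchor = d0
            break
    if anchor is None:
        return 0
    lo = hi = float(anchor)
    while hi - anchor < max_width and ink(hi + 1):
        hi += 1
    while anchor - lo < max_width and ink(lo - 1):
        lo -= 1
    return int(hi - lo) + 1


def detect_solid_wedges(
    bonds: list[Bond],
    prethin_img: BinaryImage,
    num_samples: int = 20,
    center_fraction: float = 0.6,
    min_max_width: int = 4,
    min_wedge_ratio: float = 1.0,
    min_length: float = 0.0,
) -> list[Bond]:
    """Mark degree-1 solid bonds with a wedge-shaped width profile.

    The width of the pre-thinning stroke is sampled along the central
    ``center_fraction`` of the bond; a bond is a solid wedge when the wider
    end reaches ``min_max_width`` px and the relative width change between the
    profile's two ends is at least ``min_wedge_ratio``.  Confirmed wedges get
    their endings re-derived from the full stroke extent, since thinning
    retracts the wedge tip.
    """
    out = []
    pix = prethin_img.pixels
    for bond in bonds:
        if bond.style != BondStyle.SOLID or bond.degree != 1 or bond.length < min_length:
            out.append(bond)
            continue
        u = _geom.unit_direction(bond.end1, bond.end2)
        nrm = (-u[1], u[0])
        ts = [(k + 0.5) / num_samples for k in range(num_samples)]
        crop = int(round(num_samples * (1 - center_fraction) / 2))
        ts = ts[crop : num_samples - crop]
        widths = []
        for t in ts:
            p = (
                bond.end1[0] + t * (bond.end2[0] - bond.end1[0]),
                bond.end1[1] + t * (bond.end2[1] - bond.end1[1]),
            )
            widths.append(_stroke_width(pix, p, nrm))
        start, end = widths[0], widths[-1]
        if 0 in widths:  # gaps along the strip: not a filled wedge stroke
            out.append(bond)
            continue
        if max(start, end) < min_max_width:
            out.append(bond)
            continue
        ratio = abs(start - end) / max(min(start, end), 1)
        if ratio >= min_wedge_ratio:
            e1, e2 = _stroke_extent(prethin_img, bond)
            out.append(replace(bond, style=BondStyle.SOLID_WEDGE, end1=e1, end2=e2,
                               segments=((e1, e2),)))
        else:
            out.append(bond)
    return out


def _stroke_extent(img: BinaryImage, bond: Bond, lateral: float = 8.0) -> tuple[Point, Point]:
    """Endings of the pre-thinning stroke underlying a bond, on the bond axis."""
    u = _geom.unit_direction(bond.end1, bond.end2)
    coords = img.ink_coords().astype(float)
    rel_x = coords[:, 0] - bond.end1[0]
    rel_y = coords[:, 1] - bond.end1[1]
    proj = rel_x * u[0] + rel_y * u[1]
    perp = np.abs(rel_x * -u[1] + rel_y * u[0])
    m = (perp <= lateral) & (proj >= -6) & (proj <= bond.length + 6)
    if not m.any():
        return bond.end1, bond.end2
    lo, hi = float(proj[m].min()), float(proj[m].max())
    e1 = (bond.end1[0] + u[0] * lo, bond.end1[1] + u[1] * lo)
    e2 = (bond.end1[0] + u[0] * hi, bond.end1[1] + u[1] * hi)
    return e1, e2


def _remove_on_shape_bonds(bonds: list[Bond], group_coords: np.ndarray,
                           min_fraction: float = 0.6) -> list[Bond]:
    """Drop bonds most of whose source pixels lie on the given pixel cloud."""
    if len(group_coords) == 0:
        return list(bonds)
    tree = cKDTree(group_coords.astype(float))
    kept = []
    for b in bonds:
        if len(b.coords) == 0:
            ref = np.array([b.end1, b.end2, b.center])
        else:
            ref = b.coords.astype(float)
        d, _ = tree.query(ref, k=1)
        if (d <= 2.0).mean() >= min_fraction:
            continue
        kept.append(b)
    return kept


def detect_dashed(
    bonds: list[Bond],
    symbols: list[Shape],
    thin_shapes: list[Shape],
    lmed: float,
    max_angle: float = 20.0,
    min_group: int = 4,
) -> tuple[list[Bond], list[Shape]]:
    """Build dashed bonds from groups of parallel short thin shapes.

    Thin shapes up to ``0.5*lmed`` long are paired when their centers are
    within ``0.45*lmed`` and their orientations within ``max_angle``; groups
    of at least ``min_group`` become one bond: a dashed line when the dash
    lengths are near-uniform (variance below ``(0.15*mean)^2``), otherwise a
    dashed wedge.  Bonds and symbols lying on the consumed shapes are removed.
    """
    max_len = 0.5 * lmed
    max_dist = 0.45 * lmed
    cands = []
    for s in thin_shapes:
        length, width, ang, center = _geom.oriented_extent(s.pixels)
        # robust width: thinning leaves short spurs on stroke skeletons that
        # inflate the raw extent; judge thinness on a quantile of the
        # perpendicular residuals instead
        rwidth = _robust_width(s.pixels, ang, center)
        if (
            max(s.width, s.height) <= max_len
            and min(width, rwidth) <= max(4.0, 0.12 * length + 1.5)
            # dash strokes are elongated on the bond-length scale; salt
            # specks and other compact blobs are not
            and length >= max(3.0, 0.08 * lmed)
            and length / max(min(width, rwidth), 1.0) >= 2.0
        ):
            cands.append((s, length, ang, center))
    ds = DisjointSet(range(len(cands)))
    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            if _geom.dist(cands[i][3], cands[j][3]) > max_dist:
                continue
            if _geom.angle_diff(cands[i][2], cands[j][2]) > max_angle:
                continue
            ds.merge(i, j)
    bonds = list(bonds)
    symbols = list(symbols)
    for group in sorted(ds.subsets(), key=lambda g: min(g)):
        if len(group) < min_group:
            continue
        members = [cands[i] for i in sorted(group)]
        lengths = np.array([m[1] for m in members])
        var = float(np.var(lengths))
        style = (
            BondStyle.DASHED_LINE
            if var < (0.15 * float(lengths.mean())) ** 2
            else BondStyle.DASHED_WEDGE
        )
        centers = np.array([m[3] for m in members])
        c0 = centers.mean(axis=0)
        cov = (centers - c0).T @ (centers - c0)
        vals, vecs = np.linalg.eigh(cov)
        u = vecs[:, int(np.argmax(vals))]
        proj = (centers - c0) @ u
        order = np.argsort(proj)
        spacing = float(np.mean(np.diff(np.sort(proj)))) if len(proj) > 1 else 0.0
        lo = proj[order[0]] - spacing / 2
        hi = proj[order[-1]] + spacing / 2
        e1 = (float(c0[0] + u[0] * lo), float(c0[1] + u[1] * lo))
        e2 = (float(c0[0] + u[0] * hi), float(c0[1] + u[1] * hi))
        if e2 < e1:
            e1, e2 = e2, e1
        coords = np.unique(np.vstack([m[0].pixels for m in members]), axis=0)
        bond = Bond(style=style, degree=1, end1=e1, end2=e2, coords=coords,
                    segments=((e1, e2),))
        bonds = _remove_on_shape_bonds(bonds, coords)
        member_sets = {id(m[0]) for m in members}
        symbols = [s for s in symbols if id(s) not in member_sets and
                   not _on_coords(s, coords)]
        bonds.append(bond)
    bonds.sort(key=lambda b: (b.end1, b.end2, b.degree))
    return bonds, symbols


def _robust_width(pixels: np.ndarray, axis_angle: float, center, q: float = 0.75) -> float:
    """Quantile-based perpendicular width about the shape's axis.

    Thinning a wide short bar leaves forked end caps; a quantile residual
    ignores them while still separating line-like shapes from letter blobs."""
    a = math.radians(axis_angle)
    nrm = (-math.sin(a), math.cos(a))
    resid = np.abs(
        (pixels[:, 0] - center[0]) * nrm[0] + (pixels[:, 1] - center[1]) * nrm[1]
    )
    return 2.0 * float(np.quantile(resid, q)) + 1.0


def _on_coords(shape: Shape, coords: np.ndarray, tol: float = 1.5) -> bool:
    if len(coords) == 0:
        return False
    tree = cKDTree(coords.astype(float))
    d, _ = tree.query(shape.pixels.astype(float), k=1)
    return bool((d <= tol).mean() >= 0.8)


def detect_wavy(
    bonds: list[Bond],
    symbols: list[Shape],
    lmed: float,
    min_num_circles: int = 3,
    max_curvature_var: float = (math.pi / 4) ** 2,
    veto=None,
) -> tuple[list[Bond], list[Shape]]:
    """Detect wavy (squiggle) bonds among candidate symbol shapes.

    A candidate must be elongated on the bond-length scale (oriented extents
    straddling ``lmed/2``).  Long circular arcs are detected inside it; it
    becomes a wavy bond when there are at least ``min_num_circles`` arcs,
    their centers fit a line with RMS residual at most the largest arc
    radius, the mean covered arc reaches pi, and the arc-coverage variance
    stays below ``max_curvature_var``.  Since line detection may have cut a
    squiggle into several nearby residual pieces, candidates are proximity
    clusters of the input shapes rather than single shapes.  The consumed
    shapes and any bonds sitting on them are removed.
    """
    bonds = list(bonds)
    out_symbols = []
    # cluster shapes by bbox gap; each cluster is one candidate
    gap = max(4.0, 0.15 * lmed)
    ds = DisjointSet(range(len(symbols)))
    for i in range(len(symbols)):
        for j in range(i + 1, len(symbols)):
            bi, bj = symbols[i].bbox, symbols[j].bbox
            dx = max(0, max(bi[0], bj[0]) - min(bi[2], bj[2]))
            dy = max(0, max(bi[1], bj[1]) - min(bi[3], bj[3]))
            if math.hypot(dx, dy) <= gap:
                ds.merge(i, j)
    clusters = [sorted(c) for c in ds.subsets()]
    clusters.sort(key=lambda c: c[0])
    for cluster in clusters:
        members = [symbols[i] for i in cluster]
        pixels = np.unique(np.vstack([m.pixels for m in members]), axis=0)
        s = Shape(pixels)
        length, width, _, _ = _geom.oriented_extent(s.pixels)
        if max(length, width) < lmed / 2 or min(length, width) > lmed / 2:
            out_symbols.extend(members)
            continue
        if veto is not None and veto(s):
            # caller recognizes this cluster as something else (e.g. a text
            # block validated by OCR); letter rows can mimic arc rows
            out_symbols.extend(members)
            continue
        x0, y0, x1, y1 = s.bbox
        pad = max(4, int(lmed / 4))
        sub = np.zeros((y1 - y0 + 1 + 2 * pad, x1 - x0 + 1 + 2 * pad), dtype=bool)
        sub[s.pixels[:, 1] - y0 + pad, s.pixels[:, 0] - x0 + pad] = True
        sub_img = BinaryImage(sub)
        rmax = max(4, int(lmed / 5))
        curves = detect_circles(
            sub_img,
            radius_range=(3, rmax),
            radius_step=1,
            min_arc=math.radians(120.0),
            vote_threshold=0.2,
            max_peaks_per_radius=12,
            max_radial_rms=1.8,
            min_support=0.5,
            radial_tol=2.0,
        )
        curves = _dedup_curves_by_ink(curves, sub)
        if len(curves) < min_num_circles:
            out_symbols.extend(members)
            continue
        centers = np.array([c.center for c in curves])
        # alternating arc centers must hug the bond axis: RMS residual of the
        # fitted center line may not exceed the largest arc radius
        center_rms = math.sqrt(_geom.fit_line_residual(centers))
        if center_rms > max(c.radius for c in curves):
            out_symbols.extend(members)
            continue
        # coverage per arc: the tight-tolerance estimate undercounts on wobbly
        # (upscaled, thinned) strokes; take the larger of a tight and a loose
        # radial-band measurement per arc
        arcs = np.array(
            [
                max(c.arc, measure_arc(sub_img, c.center, c.radius, radial_tol=3.5))
                for c in curves
            ]
        )
        if arcs.mean() < math.pi or float(np.var(arcs)) > max_curvature_var:
            out_symbols.extend(members)
            continue
        # fit the bond axis through the arc centers (back in image coords)
        centers_img = centers + np.array([x0 - pad, y0 - pad], dtype=float)
        c0 = centers_img.mean(axis=0)
        cov = (centers_img - c0).T @ (centers_img - c0)
        vals, vecs = np.linalg.eigh(cov)
        u = vecs[:, int(np.argmax(vals))]
        proj = (centers_img - c0) @ u
        rmean = float(np.mean([c.radius for c in curves]))
        lo, hi = float(proj.min()) - rmean, float(proj.max()) + rmean
        if hi - lo < 0.55 * lmed:
            # arcs exist but do not span a bond length: letter glyphs (S, O)
            # carry arcs too and must stay symbols
            out_symbols.extend(members)
            continue
        # squiggle arcs alternate at ~2r spacing along the axis; letter arcs
        # pile up at one or two spots (an 'O' is concentric circles)
        spots = 1
        for gap_ in np.diff(np.sort(proj)):
            if gap_ >= 1.2 * rmean:
                spots += 1
        if spots < min_num_circles:
            out_symbols.extend(members)
            continue
        e1 = (float(c0[0] + u[0] * lo), float(c0[1] + u[1] * lo))
        e2 = (float(c0[0] + u[0] * hi), float(c0[1] + u[1] * hi))
        bonds = _remove_on_shape_bonds(bonds, s.pixels)
        bonds.append(
            Bond(style=BondStyle.WAVY, degree=1, end1=e1, end2=e2,
                 coords=s.pixels, segments=((e1, e2),))
        )
    bonds.sort(key=lambda b: (b.end1, b.end2, b.degree))
    return bonds, out_symbols


def _dedup_curves_by_ink(curves, sub: np.ndarray, radial_tol: float = 2.0):
    """Greedily keep arcs by coverage, dropping ones whose ink is already
    claimed by a stronger arc (the same squiggle ink fits several circles)."""
    ys, xs = np.nonzero(sub)
    pts = np.column_stack([xs, ys]).astype(float)
    claimed = np.zeros(len(pts), dtype=bool)
    kept = []
    for c in sorted(curves, key=lambda c: (-c.arc, -c.votes, c.radius)):
        d = np.hypot(pts[:, 0] - c.center[0], pts[:, 1] - c.center[1])
        band = np.abs(d - c.radius) <= radial_tol
        n_band = band.sum()
        if n_band == 0 or (claimed[band].sum() / n_band) > 0.5:
            continue
        claimed |= band
        kept.append(c)
    return kept


def mark_aromatic_rings(
    bonds: list[Bond], circles: list[Circle], lmed: float
) -> list[Bond]:
    """Flag the single-bond polygon around each detected circle as aromatic.

    A circle's ring bonds are the bond-length-scale degree-1 solid bonds
    whose segment passes the circle at 0.8–2.5 radii; they are flagged when
    together they subtend at least 90% of the full angle at the circle center
    (i.e. they enclose it).
    """
    bonds = list(bonds)
    for circle in circles:
        ring_idx = []
        for i, b in enumerate(bonds):
            if b.style != BondStyle.SOLID or b.degree != 1 or b.length < 0.4 * lmed:
                continue
            d = _geom.point_segment_distance(circle.center, b.end1, b.end2)
            # ring edges pass the circle at roughly the polygon apothem and
            # keep both vertices near the circumradius; substituent bonds
            # radiate outward and fail the endpoint gate
            if not (0.8 * circle.radius <= d <= 2.0 * circle.radius):
                continue
            if max(
                _geom.dist(b.end1, circle.center), _geom.dist(b.end2, circle.center)
            ) > 2.6 * circle.radius:
                continue
            ring_idx.append(i)
        covered = np.zeros(360, dtype=bool)
        for i in ring_idx:
            b = bonds[i]
            a1 = math.degrees(math.atan2(b.end1[1] - circle.center[1], b.end1[0] - circle.center[0])) % 360
            a2 = math.degrees(math.atan2(b.end2[1] - circle.center[1], b.end2[0] - circle.center[0])) % 360
            span = (a2 - a1) % 360
            if span > 180:
                a1, a2 = a2, a1
                span = 360 - span
            for k in range(int(span) + 1):
                covered[int(a1 + k) % 360] = True
        if covered.mean() >= 0.9 and ring_idx:
            for i in ring_idx:
                bonds[i] = replace(bonds[i], style=BondStyle.AROMATIC)
        else:
            log.warning("circle at %s has no enclosing bond polygon; discarded", circle.center)
    return bonds
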