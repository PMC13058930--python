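"""Fragment-merging (FM) adaptive line detection.

Classical line Hough transforms trade endpoint accuracy against spurious
overlapping detections: coarse resolutions miss short bond lines, fine
resolutions shatter every stroke into fragments.  The FM detector embraces
the fine-resolution regime (2 px / 2 degree accumulator) and repairs it in
three stages: (1) walk each accumulator peak line and vectorize the connected
ink runs found in a 5-pixel window around it into *line fragments*;
(2) pair fragments that agree in angle, lie on each other's carrier line and
either overlap along it or are bridged by ink; (3) merge pair groups with
union-find and emit one line per group, its endpoints taken from the extreme
member endpoints.  Detected lines finally pass a relative length filter
(shorter than one tenth of the mean length is discarded), since bond lines in
one structure image have a tight length distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import DisjointSet

from . import _geom
from .raster import BinaryImage

Point = tuple[float, float]


@dataclass(frozen=True)
class HoughLine:
    """A line in normal form r = x*cos(theta) + y*sin(theta); theta in degrees."""

    r: float
    theta: float
    votes: int = 0


@dataclass(frozen=True)
class LineFragment:
    """A connected ink run found along one Hough line."""

    end1: tuple[int, int]
    end2: tuple[int, int]
    pixels: np.ndarray  # (N, 2) int (x, y), lexicographically sorted

    @property
    def length(self) -> float:
        return _geom.dist(self.end1, self.end2)

    @property
    def angle(self) -> float:
        return _geom.angle_of(self.end1, self.end2)

    @property
    def center(self) -> Point:
        return (
            (self.end1[0] + self.end2[0]) / 2.0,
            (self.end1[1] + self.end2[1]) / 2.0,
        )


@dataclass(frozen=True)
class DetectedLine:
    """A merged line segment; endpoints are extreme member-fragment endpoints."""

    end1: tuple[float, float]
    end2: tuple[float, float]
    pixels: np.ndarray  # union of member fragment pixels

    @property
    def length(self) -> float:
        return _geom.dist(self.end1, self.end2)

    @property
    def angle(self) -> float:
        return _geom.angle_of(self.end1, self.end2)

    @property
    def center(self) -> Point:
        return (
            (self.end1[0] + self.end2[0]) / 2.0,
            (self.end1[1] + self.end2[1]) / 2.0,
        )


def hough_peaks(
    img: BinaryImage,
    rho_res: float = 2.0,
    theta_res: float = 2.0,
    min_votes: int = 10,
) -> list[HoughLine]:
    """High-resolution line Hough transform returning local accumulator peaks.

    Peaks are 3x3 local maxima with at least ``min_votes`` votes, ordered by
    descending vote count then (r, theta).
    """
    coords = img.ink_coords().astype(float)
    if len(coords) == 0:
        return []
    thetas_deg = np.arange(0.0, 180.0, theta_res)
    thetas = np.deg2rad(thetas_deg)
    cos_t, sin_t = np.cos(thetas), np.sin(thetas)
    diag = math.hypot(img.width, img.height)
    n_rho = int(2 * math.ceil(diag / rho_res)) + 1
    rho_offset = n_rho // 2
    # vote: rho = x cos(theta) + y sin(theta), binned at rho_res
    rhos = coords[:, 0:1] * cos_t[None, :] + coords[:, 1:2] * sin_t[None, :]
    rho_idx = np.rint(rhos / rho_res).astype(int) + rho_offset
    acc = np.zeros((len(thetas), n_rho), dtype=np.int32)
    t_idx = np.broadcast_to(np.arange(len(thetas))[None, :], rho_idx.shape)
    np.add.at(acc, (t_idx.ravel(), rho_idx.ravel()), 1)
    # NMS footprint: +-1 theta bin, +-2 rho bins (parallel multibond lines sit
    # at least 3 rho bins apart at the default 2 px resolution)
    local_max = acc == ndimage.maximum_filter(acc, size=(3, 5))
    ti, ri = np.nonzero(local_max & (acc >= min_votes))
    votes = acc[ti, ri]
    lines = [
        HoughLine(
            r=float((r - rho_offset) * rho_res),
            theta=float(thetas_deg[t]),
            votes=int(v),
        )
        for t, r, v in zip(ti, ri, votes)
    ]
    lines.sort(key=lambda l: (-l.votes, l.r, l.theta))
    return lines


def _fragment_from_pixels(pts: np.ndarray, direction: Point) -> LineFragment:
    proj = pts[:, 0] * direction[0] + pts[:, 1] * direction[1]
    i1, i2 = int(np.argmin(proj)), int(np.argmax(proj))
    pts_sorted = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    return LineFragment(
        end1=(int(pts[i1, 0]), int(pts[i1, 1])),
        end2=(int(pts[i2, 0]), int(pts[i2, 1])),
        pixels=pts_sorted,
    )


def _regroup_by_connectivity(pts: np.ndarray) -> list[np.ndarray]:
    pset = {(int(x), int(y)) for x, y in pts}
    ds = DisjointSet(pset)
    for (x, y) in pset:
        for nx_ in (x - 1, x, x + 1):
            for ny in (y - 1, y, y + 1):
                if (nx_, ny) != (x, y) and (nx_, ny) in pset:
                    ds.merge((x, y), (nx_, ny))
    return [np.array(sorted(g), dtype=int) for g in ds.subsets()]


def _straighten(pts: np.ndarray, max_resid: float = 1.5) -> list[np.ndarray]:
    """Trim pixels that stray from the group's own fitted line.

    At stroke junctions the scan window of one line picks up connected pixels
    of a crossing stroke; those tails bend the fragment.  Iteratively fit a
    PCA line, drop pixels with larger perpendicular residual, and split the
    remainder back into connected groups.
    """
    out = []
    stack = [pts]
    guard = 0
    while stack and guard < 200:
        guard += 1
        grp = stack.pop()
        if len(grp) < 2:
            continue
        c = grp.mean(axis=0)
        centered = grp - c
        cov = centered.T @ centered / len(grp)
        vals, vecs = np.linalg.eigh(cov)
        normal = vecs[:, int(np.argmin(vals))]
        resid = np.abs(centered @ normal)
        keep = resid <= max_resid
        if keep.all():
            out.append(grp)
            continue
        kept = grp[keep]
        if len(kept) < 2:
            continue
        stack.extend(_regroup_by_connectivity(kept))
    return out


def collect_fragments(
    img: BinaryImage, lines: list[HoughLine], window: int = 2
) -> list[LineFragment]:
    """Vectorize each Hough line into connected ink fragments.

    Walks the theoretical line along its dominant axis, collecting ink pixels
    whose off-axis coordinate is within ``window`` (a 5-pixel search window by
    default) of the predicted one, then splits the collected set into
    8-connected groups, one fragment each.
    """
    pix = img.pixels
    h, w = pix.shape
    fragments: list[LineFragment] = []
    seen: set[bytes] = set()
    for line in lines:
        th = math.radians(line.theta)
        c, s = math.cos(th), math.sin(th)
        collected: set[tuple[int, int]] = set()
        if abs(s) >= abs(c):  # closer to horizontal: walk x, predict y
            xs = np.arange(w)
            y0 = (line.r - xs * c) / s
            yc = np.rint(y0).astype(int)
            for dy in range(-window, window + 1):
                yy = yc + dy
                ok = (yy >= 0) & (yy < h)
                hit = np.zeros(w, dtype=bool)
                hit[ok] = pix[yy[ok], xs[ok]]
                for x in np.nonzero(hit)[0]:
                    collected.add((int(x), int(yy[x])))
        else:  # closer to vertical: walk y, predict x
            ys = np.arange(h)
            x0 = (line.r - ys * s) / c
            xc = np.rint(x0).astype(int)
            for dx in range(-window, window + 1):
                xx = xc + dx
                ok = (xx >= 0) & (xx < w)
                hit = np.zeros(h, dtype=bool)
                hit[ok] = pix[ys[ok], xx[ok]]
                for y in np.nonzero(hit)[0]:
                    collected.add((int(xx[y]), int(y)))
        if len(collected) < 2:
            continue
        # group by 8-connectivity within the collected set
        ds = DisjointSet(collected)
        for (x, y) in collected:
            for nx in (x - 1, x, x + 1):
                for ny in (y - 1, y, y + 1):
                    if (nx, ny) != (x, y) and (nx, ny) in collected:
                        ds.merge((x, y), (nx, ny))
        direction = (-s, c)
        for group in ds.subsets():
            if len(group) < 2:
                continue
            pts = np.array(sorted(group), dtype=int)
            for sub in _straighten(pts):
                frag = _fragment_from_pixels(sub, direction)
                if frag.length < 1.0:  # degenerate along the scan direction
                    continue
                key = frag.pixels.tobytes()
                if key in seen:
                    continue
                seen.add(key)
                fragments.append(frag)
    fragments.sort(key=lambda f: (f.end1, f.end2))
    return fragments


def pair_fragments(
    fragments: list[LineFragment],
    img: BinaryImage,
    angle_threshold: float = 6.0,
    dist_threshold: float = 3.0,
    n_samples: int = 16,
) -> set[tuple[int, int]]:
    """Emit index pairs of fragments that belong to the same bond line.

    A pair requires (i) angle difference <= ``angle_threshold``, (ii) one
    fragment's center within ``dist_threshold`` of the other's carrier line
    (minimum over both directions), and (iii) overlap along the mean line
    direction or an ink path between their nearest endpoints (every one of
    ``n_samples`` evenly spaced points within 1 px of ink).
    """
    n = len(fragments)
    if n < 2:
        return set()
    e1 = np.array([f.end1 for f in fragments], dtype=float)
    e2 = np.array([f.end2 for f in fragments], dtype=float)
    centers = (e1 + e2) / 2.0
    deltas = e2 - e1
    lengths = np.hypot(deltas[:, 0], deltas[:, 1])
    lengths[lengths == 0] = 1e-9
    angles = np.degrees(np.arctan2(deltas[:, 1], deltas[:, 0])) % 180.0

    ad = np.abs(angles[:, None] - angles[None, :]) % 180.0
    ad = np.minimum(ad, 180.0 - ad)
    ii, jj = np.nonzero(np.triu(ad <= angle_threshold, k=1))
    if len(ii) == 0:
        return set()

    def center_to_line(ci, li):  # distance of centers[ci] to carrier of li
        cr = (
            deltas[li, 0] * (centers[ci, 1] - e1[li, 1])
            - deltas[li, 1] * (centers[ci, 0] - e1[li, 0])
        )
        return np.abs(cr) / lengths[li]

    dmin = np.minimum(center_to_line(ii, jj), center_to_line(jj, ii))
    keep = dmin <= dist_threshold
    ii, jj = ii[keep], jj[keep]
    if len(ii) == 0:
        return set()

    # (iii) projection overlap along the mean direction
    ang_i = np.radians(angles[ii])
    u_i = np.column_stack([np.cos(ang_i), np.sin(ang_i)])
    ang_j = np.radians(angles[jj])
    u_j = np.column_stack([np.cos(ang_j), np.sin(ang_j)])
    flip = (u_i * u_j).sum(axis=1) < 0
    u_j[flip] *= -1.0
    u = u_i + u_j
    norm = np.hypot(u[:, 0], u[:, 1])
    norm[norm == 0] = 1.0
    u /= norm[:, None]
    pi1 = (e1[ii] * u).sum(axis=1)
    pi2 = (e2[ii] * u).sum(axis=1)
    pj1 = (e1[jj] * u).sum(axis=1)
    pj2 = (e2[jj] * u).sum(axis=1)
    lo_i, hi_i = np.minimum(pi1, pi2), np.maximum(pi1, pi2)
    lo_j, hi_j = np.minimum(pj1, pj2), np.maximum(pj1, pj2)
    overlapped = (lo_i <= hi_j) & (lo_j <= hi_i)

    pairs = {(int(a), int(b)) for a, b in zip(ii[overlapped], jj[overlapped])}

    # remaining pairs: sampled ink path between nearest endpoints.  The
    # displacement between the fragments must continue their common direction
    # (a collinearity gate: staircase steps of a slanted stroke are parallel
    # but laterally offset, and must not chain into one line).
    ri, rj = ii[~overlapped], jj[~overlapped]
    if len(ri):
        disp = centers[rj] - centers[ri]
        disp_ang = np.degrees(np.arctan2(disp[:, 1], disp[:, 0])) % 180.0
        ok = np.ones(len(ri), dtype=bool)
        for other in (angles[ri], angles[rj]):
            d = np.abs(disp_ang - other) % 180.0
            ok &= np.minimum(d, 180.0 - d) <= angle_threshold + 4.0
        ri, rj = ri[ok], rj[ok]
    if len(ri):
        from scipy.ndimage import binary_dilation

        near_ink = binary_dilation(img.pixels, structure=np.ones((3, 3), dtype=bool))
        combos = np.stack(
            [
                np.hypot(*(e1[ri] - e1[rj]).T),
                np.hypot(*(e1[ri] - e2[rj]).T),
                np.hypot(*(e2[ri] - e1[rj]).T),
                np.hypot(*(e2[ri] - e2[rj]).T),
            ],
            axis=1,
        )
        choice = np.argmin(combos, axis=1)
        p1 = np.where(choice[:, None] < 2, e1[ri], e2[ri])
        p2 = np.where((choice % 2)[:, None] == 0, e1[rj], e2[rj])
        ts = (np.arange(n_samples) + 0.5) / n_samples
        xs = p1[:, 0:1] + ts[None, :] * (p2[:, 0] - p1[:, 0])[:, None]
        ys = p1[:, 1:2] + ts[None, :] * (p2[:, 1] - p1[:, 1])[:, None]
        xs = np.clip(np.rint(xs).astype(int), 0, img.width - 1)
        ys = np.clip(np.rint(ys).astype(int), 0, img.height - 1)
        bridged = near_ink[ys, xs].all(axis=1)
        pairs.update((int(a), int(b)) for a, b in zip(ri[bridged], rj[bridged]))
    return pairs


def merge_groups(
    pairs: set[tuple[int, int]], fragments: list[LineFragment]
) -> list[DetectedLine]:
    """Union-find closure of fragment pairs; one merged line per group."""
    if not fragments:
        return []
    ds = DisjointSet(range(len(fragments)))
    for i, j in sorted(pairs):
        ds.merge(i, j)
    lines = []
    for group in sorted(ds.subsets(), key=lambda g: min(g)):
        members = [fragments[i] for i in sorted(group)]
        pts = np.unique(np.vstack([f.pixels for f in members]), axis=0)
        ends = [f.end1 for f in members] + [f.end2 for f in members]
        xs = [e[0] for e in ends]
        ys = [e[1] for e in ends]
        if (max(xs) - min(xs)) > (max(ys) - min(ys)):
            e1 = min(ends)  # leftmost (ties: lowest y)
            e2 = max(ends)  # rightmost
        else:
            e1 = min(ends, key=lambda e: (e[1], e[0]))  # topmost
            e2 = max(ends, key=lambda e: (e[1], e[0]))  # bottommost
        if e1 == e2:
            continue
        lines.append(DetectedLine(end1=e1, end2=e2, pixels=pts))
    lines.sort(key=lambda l: (l.end1, l.end2))
    return lines


def filter_short(lines: list[DetectedLine]) -> list[DetectedLine]:
    """Drop lines shorter than one tenth of the mean detected length."""
    if not lines:
        return []
    mean_len = float(np.mean([l.length for l in lines]))
    return [l for l in lines if l.length >= mean_len / 10.0]


def _dedup_overlapping(lines: list[DetectedLine]) -> list[DetectedLine]:
    """Drop the shorter of two lines covering the same stroke.

    A shorter line is redundant when it shares most of its pixels with a
    longer one, or when it runs inside the longer line's 2.5-px corridor
    with a compatible angle (staircase pixels of one stroke claimed by two
    neighbouring Hough peaks need not share exact pixels).
    """
    keep = [True] * len(lines)
    order = sorted(range(len(lines)), key=lambda i: -lines[i].length)
    sets = [set(map(tuple, l.pixels)) for l in lines]
    for a_pos, i in enumerate(order):
        if not keep[i]:
            continue
        li = lines[i]
        u = _geom.unit_direction(li.end1, li.end2)
        for j in order[a_pos + 1 :]:
            if not keep[j]:
                continue
            lj = lines[j]
            inter = len(sets[i] & sets[j])
            if inter > 0.5 * min(len(sets[i]), len(sets[j])):
                keep[j] = False
                continue
            # angle agreement is meaningless for very short lines (quantized)
            if lj.length > 10.0 and _geom.angle_diff(li.angle, lj.angle) > 8.0:
                continue
            lat1 = _geom.point_line_distance(lj.end1, li.end1, li.end2)
            lat2 = _geom.point_line_distance(lj.end2, li.end1, li.end2)
            if max(lat1, lat2) > 3.2:
                continue
            p1 = _geom.project_onto(lj.end1, li.end1, u)
            p2 = _geom.project_onto(lj.end2, li.end1, u)
            if min(p1, p2) >= -2.0 and max(p1, p2) <= li.length + 2.0:
                keep[j] = False
    return [l for k, l in zip(keep, lines) if k]


def _extend_endpoints(img: BinaryImage, line: DetectedLine,
                      lateral: float = 1.5, max_ext: float = 6.0) -> DetectedLine:
    """Push line endings outward along the carrier while skeleton ink continues.

    Fragment straightening trims rounded junction corners, leaving merged
    lines a couple of pixels short of the true stroke meeting point; this
    walks the skeleton back out (bounded, so isolated segments stay put).
    """
    coords = img.ink_coords().astype(float)
    u = _geom.unit_direction(line.end1, line.end2)
    rel_x = coords[:, 0] - line.end1[0]
    rel_y = coords[:, 1] - line.end1[1]
    proj = rel_x * u[0] + rel_y * u[1]
    perp = np.abs(-rel_x * u[1] + rel_y * u[0])
    corridor = perp <= lateral
    L = line.length
    hi = 0.0
    for _ in range(6):
        m = corridor & (proj > L + hi) & (proj <= L + hi + 2.0) & (proj <= L + max_ext)
        if not m.any():
            break
        hi = float(proj[m].max()) - L
    lo = 0.0
    for _ in range(6):
        m = corridor & (proj < lo) & (proj >= lo - 2.0) & (proj >= -max_ext)
        if not m.any():
            break
        lo = float(proj[m].min())
    if hi == 0.0 and lo == 0.0:
        return line
    e1 = (line.end1[0] + u[0] * lo, line.end1[1] + u[1] * lo)
    e2 = (line.end1[0] + u[0] * (L + hi), line.end1[1] + u[1] * (L + hi))
    return DetectedLine(end1=e1, end2=e2, pixels=line.pixels)


def _refit_carrier(line: DetectedLine) -> DetectedLine:
    """Re-derive endpoints from a total-least-squares fit of the line pixels.

    Member-endpoint selection is quantized to single pixels; fitting the whole
    pixel set averages out staircase noise in both the lateral offset and the
    orientation.
    """
    pts = line.pixels.astype(float)
    if len(pts) < 4:
        return line
    c = pts.mean(axis=0)
    centered = pts - c
    cov = centered.T @ centered / len(pts)
    vals, vecs = np.linalg.eigh(cov)
    u = vecs[:, int(np.argmax(vals))]
    proj = centered @ u
    e1 = (float(c[0] + u[0] * proj.min()), float(c[1] + u[1] * proj.min()))
    e2 = (float(c[0] + u[0] * proj.max()), float(c[1] + u[1] * proj.max()))
    if e2 < e1:
        e1, e2 = e2, e1
    return DetectedLine(end1=e1, end2=e2, pixels=line.pixels)


def _skeleton_junctions(img: BinaryImage) -> np.ndarray:
    """Skeleton pixels with three or more ink neighbours (stroke meeting
    points), as (x, y) float rows."""
    from scipy.ndimage import convolve

    pix = img.pixels.astype(np.int8)
    neigh = convolve(
        pix, np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.int8), mode="constant"
    )
    ys, xs = np.nonzero((pix > 0) & (neigh >= 3))
    junctions = np.column_stack([xs, ys]).astype(float)
    corners = _skeleton_corners(img)
    if len(corners):
        junctions = np.vstack([junctions, corners]) if len(junctions) else corners
    return junctions


def _skeleton_corners(img: BinaryImage, steps: int = 4,
                      max_angle: float = 150.0) -> np.ndarray:
    """Degree-2 skeleton pixels where the path bends sharply (stroke corners)."""
    pset = {(int(x), int(y)) for x, y in img.ink_coords()}

    def neighbors(p):
        x, y = p
        return [
            (x + dx, y + dy)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            if (dx or dy) and (x + dx, y + dy) in pset
        ]

    corners = []
    for p in pset:
        nb = neighbors(p)
        if len(nb) != 2:
            continue
        arms = []
        for start in nb:
            prev, cur = p, start
            for _ in range(steps - 1):
                nxt = [q for q in neighbors(cur) if q != prev]
                if len(nxt) != 1:
                    break
                prev, cur = cur, nxt[0]
            arms.append((cur[0] - p[0], cur[1] - p[1]))
        (ax, ay), (bx, by) = arms
        na, nb_ = math.hypot(ax, ay), math.hypot(bx, by)
        if na == 0 or nb_ == 0:
            continue
        cosang = (ax * bx + ay * by) / (na * nb_)
        ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
        if ang < max_angle:
            corners.append(p)
    return np.array(corners, dtype=float) if corners else np.empty((0, 2))


def _trim_to_junctions(line: DetectedLine, junctions: np.ndarray,
                       lateral_tol: float = 2.0, window: float = 4.0) -> DetectedLine:
    """Pull back an ending that ran slightly past an on-carrier junction.

    The scan window collects a couple of the crossing stroke's pixels beyond a
    vertex; the junction pixel itself marks where the strokes actually meet.
    """
    if len(junctions) == 0:
        return line
    u = _geom.unit_direction(line.end1, line.end2)
    rel = junctions - np.array(line.end1, dtype=float)
    proj = rel @ np.array(u)
    lat = np.abs(rel @ np.array([-u[1], u[0]]))
    on = lat <= lateral_tol
    if not on.any():
        return line
    L = line.length
    win = min(window, 0.15 * L)
    e1, e2 = line.end1, line.end2
    near1 = on & (proj > 0) & (proj <= win)
    if near1.any():
        k = int(np.argmin(np.where(near1, proj, np.inf)))
        e1 = (float(junctions[k, 0]), float(junctions[k, 1]))
    near2 = on & (proj < L) & (L - proj <= win)
    if near2.any():
        k = int(np.argmin(np.where(near2, L - proj, np.inf)))
        e2 = (float(junctions[k, 0]), float(junctions[k, 1]))
    if e1 == e2:
        return line
    return DetectedLine(end1=e1, end2=e2, pixels=line.pixels)


def fragment_merging(
    img: BinaryImage,
    rho_res: float = 2.0,
    theta_res: float = 2.0,
    min_votes: int = 10,
    angle_threshold: float = 6.0,
    dist_threshold: float = 3.0,
) -> list[DetectedLine]:
    """Full FM pipeline: Hough peaks -> fragments -> pairing -> merge -> filters."""
    peaks = hough_peaks(img, rho_res=rho_res, theta_res=theta_res, min_votes=min_votes)
    frags = collect_fragments(img, peaks)
    pairs = pair_fragments(frags, img, angle_threshold, dist_threshold)
    lines = merge_groups(pairs, frags)
    lines = _dedup_overlapping(lines)
    # support density: a genuine line carries about one ink pixel per unit
    # length (1/sqrt(2) for diagonals); sparse merges that hop between
    # strokes through a junction are dropped
    lines = [l for l in lines if len(l.pixels) >= 0.6 * l.length]
    junctions = _skeleton_junctions(img)
    lines = [
        _trim_to_junctions(_extend_endpoints(img, _refit_carrier(l)), junctions)
        for l in lines
    ]
    return filter_short(lines)
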