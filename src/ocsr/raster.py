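"""Raster-level primitives: binarization, preprocessing, thinning, connected
shapes and circle detection.

Conventions used throughout the package: images are boolean numpy arrays of
shape ``(height, width)`` indexed ``[y, x]`` with ``True`` = ink, origin at
the top-left corner and y growing downward.  Public coordinates are always
``(x, y)`` pairs.  The y axis is only flipped at Molfile export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize
from skimage.transform import hough_circle

from .errors import BlankImageError


@dataclass(frozen=True)
class BinaryImage:
    """An ink/background raster.  ``pixels[y, x]`` is True on ink."""

    pixels: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "pixels", np.ascontiguousarray(self.pixels, dtype=bool))

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def ink_count(self) -> int:
        return int(self.pixels.sum())

    def ink_coords(self) -> np.ndarray:
        """Ink pixel coordinates as an (N, 2) int array of (x, y) rows."""
        ys, xs = np.nonzero(self.pixels)
        return np.column_stack([xs, ys])

    def copy(self) -> "BinaryImage":
        return BinaryImage(self.pixels.copy())


@dataclass(frozen=True)
class Shape:
    """An 8-connected set of ink pixels with its tight bounding box."""

    pixels: np.ndarray  # (N, 2) int array of (x, y), lexicographically sorted

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        xs, ys = self.pixels[:, 0], self.pixels[:, 1]
        return int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max())

    @property
    def width(self) -> int:
        b = self.bbox
        return b[2] - b[0] + 1

    @property
    def height(self) -> int:
        b = self.bbox
        return b[3] - b[1] + 1

    @property
    def area(self) -> int:
        return len(self.pixels)

    @property
    def center(self) -> tuple[float, float]:
        c = self.pixels.mean(axis=0)
        return float(c[0]), float(c[1])

    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(x), int(y)) for x, y in self.pixels}


@dataclass(frozen=True)
class Circle:
    """A detected circular curve: center, radius, covered arc and votes."""

    center: tuple[float, float]
    radius: float
    arc: float  # covered angular extent, radians, in [0, 2*pi]
    votes: float = 0.0


def binarize(image: np.ndarray, threshold: str | int = "otsu") -> BinaryImage:
    """Convert a grayscale raster to an ink-on-white binary image.

    ``threshold`` is either ``"otsu"`` (global Otsu threshold) or a fixed
    integer; pixels strictly darker than the threshold become ink.  If ink
    would cover more than half the raster the polarity is inverted, enforcing
    the white-background convention.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=2)
    if arr.dtype == bool:
        ink = arr.copy()  # already ink/background
    else:
        arr = arr.astype(float)
        if arr.max() == arr.min():
            ink = np.zeros(arr.shape, dtype=bool)
        else:
            thr = float(threshold_otsu(arr)) if threshold == "otsu" else float(threshold)
            ink = arr < thr
    if ink.mean() > 0.5:
        ink = ~ink
    return BinaryImage(ink)


def trim_pad_upscale(
    img: BinaryImage, pad: int = 16, min_dim: int = 300
) -> tuple[BinaryImage, int]:
    """Trim background borders to the ink bbox, pad, and upscale small images.

    Returns the new image and the integer nearest-neighbour upscale factor
    (1 when no upscaling was needed).  Padding is applied after upscaling so
    the border is exactly ``pad`` pixels in the output.
    """
    if img.ink_count == 0:
        raise BlankImageError("blank image: no ink pixels to trim")
    ys, xs = np.nonzero(img.pixels)
    core = img.pixels[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
    scale = 1
    if max(core.shape) < min_dim:
        scale = int(math.ceil(min_dim / max(core.shape)))
        core = np.kron(core, np.ones((scale, scale), dtype=bool))
    out = np.zeros((core.shape[0] + 2 * pad, core.shape[1] + 2 * pad), dtype=bool)
    if pad:
        out[pad:-pad, pad:-pad] = core
    else:
        out = core.copy()
    return BinaryImage(out), scale


def thin(img: BinaryImage) -> BinaryImage:
    """Zhang–Suen thinning: reduce strokes to 1-pixel-wide skeletons."""
    if img.ink_count == 0:
        return img.copy()
    return BinaryImage(skeletonize(img.pixels, method="zhang"))


def extract_shapes(img: BinaryImage) -> list[Shape]:
    """Partition ink pixels into 8-connected shapes, deterministically ordered."""
    if img.ink_count == 0:
        return []
    labels, n = ndimage.label(img.pixels, structure=np.ones((3, 3), dtype=int))
    shapes = []
    ys, xs = np.nonzero(img.pixels)
    lab = labels[ys, xs]
    order = np.lexsort((xs, ys))  # stable pixel order
    ys, xs, lab = ys[order], xs[order], lab[order]
    for i in range(1, n + 1):
        m = lab == i
        pts = np.column_stack([xs[m], ys[m]])
        pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
        shapes.append(Shape(pts))
    shapes.sort(key=lambda s: (s.bbox, tuple(s.pixels[0])))
    return shapes


def measure_arc(img: BinaryImage, center: tuple[float, float], radius: float,
                radial_tol: float = 2.0) -> float:
    """Angular coverage (radians) of ink along a circle.

    Ink pixels whose distance to the center is within ``radial_tol`` of the
    radius are binned into angular sectors and coverage is the occupied
    fraction of the full angle.  The sector width scales with the radius
    (one pixel step along a small circle subtends several degrees, so fixed
    1-degree bins would undercount small arcs).
    """
    coords = img.ink_coords().astype(float)
    if len(coords) == 0:
        return 0.0
    dx = coords[:, 0] - center[0]
    dy = coords[:, 1] - center[1]
    r = np.hypot(dx, dy)
    on = np.abs(r - radius) <= radial_tol
    if not on.any():
        return 0.0
    width_deg = int(min(20.0, max(1.0, math.ceil(70.0 / max(radius, 1.0)))))
    n_bins = max(1, 360 // width_deg)
    ang = np.degrees(np.arctan2(dy[on], dx[on])) % 360.0
    bins = np.unique((ang / 360.0 * n_bins).astype(int))
    return min(2.0 * math.pi, len(bins) * (2.0 * math.pi / n_bins))


def detect_circles(
    img: BinaryImage,
    radius_range: tuple[int, int] = (10, 90),
    min_arc: float = math.radians(200.0),
    vote_threshold: float = 0.3,
    max_peaks_per_radius: int = 8,
    radius_step: int = 2,
    radial_tol: float = 3.0,
    max_radial_rms: float = 1.2,
    min_support: float = 0.7,
) -> list[Circle]:
    """Circle Hough transform with non-maximum suppression and an arc gate.

    Voting runs over (a, b, r); normalized accumulator peaks above
    ``vote_threshold`` survive NMS (a weaker peak is suppressed within
    ``max(3, 0.25*r)`` px center distance and ``0.25*r`` radius of a stronger
    one) and must cover more than ``min_arc`` radians of measured ink to be
    returned.  The default gate (200°) keeps only curves clearly longer than a
    half circle, allowing for sector-bin bleed at the arc ends.
    """
    rmin, rmax = radius_range
    rmax = min(rmax, max(rmin, min(img.height, img.width) // 2))
    if img.ink_count == 0 or rmax < rmin:
        return []
    radii = np.arange(rmin, rmax + 1, radius_step)
    acc = hough_circle(img.pixels, radii)  # (R, H, W), normalized
    candidates = []
    for ri, r in enumerate(radii):
        plane = acc[ri]
        local_max = plane == ndimage.maximum_filter(plane, size=5)
        ys, xs = np.nonzero(local_max & (plane >= vote_threshold))
        votes = plane[ys, xs]
        order = np.argsort(-votes, kind="stable")[:max_peaks_per_radius]
        for k in order:
            candidates.append((float(votes[k]), int(r), int(xs[k]), int(ys[k])))
    # strongest first; deterministic tie-break on (r, x, y)
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    kept: list[tuple[float, int, int, int]] = []
    for v, r, x, y in candidates:
        suppressed = False
        for v2, r2, x2, y2 in kept:
            if (
                math.hypot(x - x2, y - y2) <= max(3.0, 0.25 * r2)
                and abs(r - r2) <= 0.25 * r2
            ):
                suppressed = True
                break
        if not suppressed:
            kept.append((v, r, x, y))
    out = []
    coords_all = img.ink_coords().astype(float)
    for v, r, x, y in kept:
        cx, cy, cr = refine_circle(img, (float(x), float(y)), float(r), radial_tol + 1.0)
        if cr <= 0:
            continue
        arc = measure_arc(img, (cx, cy), cr, radial_tol=radial_tol)
        if arc <= min_arc:
            continue
        # circularity gates: straight strokes grazing the annulus mimic arcs
        # but sit loosely in it (high radial RMS) with thin pixel support
        d = np.hypot(coords_all[:, 0] - cx, coords_all[:, 1] - cy)
        band = np.abs(d - cr) <= radial_tol
        if not band.any():
            continue
        rms = float(np.sqrt(((d[band] - cr) ** 2).mean()))
        support = band.sum() / max(arc * cr, 1.0)
        if rms > max_radial_rms or support < min_support:
            continue
        out.append(Circle(center=(cx, cy), radius=cr, arc=arc, votes=v))
    # refinement can collapse two coarse peaks onto one circle: dedup again
    deduped: list[Circle] = []
    for c in sorted(out, key=lambda c: (-c.votes, c.radius, c.center)):
        if any(
            math.hypot(c.center[0] - d.center[0], c.center[1] - d.center[1])
            <= max(3.0, 0.25 * d.radius)
            and abs(c.radius - d.radius) <= 0.25 * d.radius
            for d in deduped
        ):
            continue
        deduped.append(c)
    return deduped


def refine_circle(
    img: BinaryImage,
    center: tuple[float, float],
    radius: float,
    radial_tol: float = 4.0,
    iterations: int = 3,
) -> tuple[float, float, float]:
    """Least-squares re-fit of a circle against nearby ink pixels.

    Accumulator peaks are quantized to the voting grid; thick or upscaled
    strokes need a sub-bin estimate before masking.  Uses the algebraic
    (Kasa) fit restricted to pixels within ``radial_tol`` of the current ring.
    """
    coords = img.ink_coords().astype(float)
    if len(coords) == 0:
        return center[0], center[1], radius
    cx, cy, r = float(center[0]), float(center[1]), float(radius)
    for _ in range(iterations):
        d = np.hypot(coords[:, 0] - cx, coords[:, 1] - cy)
        on = np.abs(d - r) <= radial_tol
        if on.sum() < 8:
            break
        x, y = coords[on, 0], coords[on, 1]
        a_mat = np.column_stack([x, y, np.ones(len(x))])
        rhs = x * x + y * y
        sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
        cx_new, cy_new = sol[0] / 2.0, sol[1] / 2.0
        r_new = math.sqrt(max(sol[2] + cx_new**2 + cy_new**2, 1e-9))
        if abs(cx_new - cx) + abs(cy_new - cy) + abs(r_new - r) < 0.05:
            cx, cy, r = cx_new, cy_new, r_new
            break
        cx, cy, r = cx_new, cy_new, r_new
    return cx, cy, r


def circle_ring_coords(
    img: BinaryImage, circle: Circle, radial_tol: float = 2.0
) -> np.ndarray:
    """Ink pixels of ``img`` lying on the circle's ring (within radial_tol)."""
    coords = img.ink_coords()
    if len(coords) == 0:
        return coords
    dx = coords[:, 0] - circle.center[0]
    dy = coords[:, 1] - circle.center[1]
    on = np.abs(np.hypot(dx, dy) - circle.radius) <= radial_tol
    return coords[on]


def mask_pixels(img: BinaryImage, pixels) -> BinaryImage:
    """Return a copy of ``img`` with the listed (x, y) pixels set to background."""
    pts = np.asarray(list(pixels) if not isinstance(pixels, np.ndarray) else pixels)
    out = img.pixels.copy()
    if pts.size == 0:
        return BinaryImage(out)
    pts = pts.reshape(-1, 2).astype(int)
    if (
        (pts[:, 0] < 0).any()
        or (pts[:, 0] >= img.width).any()
        or (pts[:, 1] < 0).any()
        or (pts[:, 1] >= img.height).any()
    ):
        raise ValueError("mask_pixels: pixel outside image bounds")
    out[pts[:, 1], pts[:, 0]] = False
    return BinaryImage(out)
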