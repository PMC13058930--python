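"""Symbol handling: shape grouping, script-role classification, OCR and
superatom parsing, plus the semi-open-loop false-positive corrections.

Bond detection inevitably claims glyph strokes (the vertical bars of H, N, l)
and occasionally leaves bond strokes among the symbol shapes.  The two
``correct_*`` operations re-assign those pixels: non-thin shapes that OCR as a
valid chemical symbol reclaim their strokes from spurious bonds, thin shapes
stay bonds only when part of a multibond or pointing at a symbol, and thin
oblique symbol shapes are restored as bonds.

OCR is a pluggable backend.  The shipped default is a deterministic template
matcher keyed to the embedded fixture font (hermetic, no external engine);
an adapter for an external OCR engine is provided for real-world scans.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from scipy.cluster.hierarchy import DisjointSet
from scipy.spatial import cKDTree
from skimage.transform import resize

from . import _geom, font
from .bonds import Bond, BondStyle
from .raster import BinaryImage, Shape, extract_shapes

log = logging.getLogger(__name__)

# IUPAC element symbols (order irrelevant; lookup set)
ELEMENTS = set(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U""".split()
)


class OcrBackend(Protocol):
    """Minimal OCR interface: binary block image in, (text, confidence) out."""

    def recognize(self, block: np.ndarray) -> tuple[str, float]: ...


class StubOcr:
    """Deterministic template-matching OCR keyed to the embedded bitmap font.

    Each 8-connected component of the block is downsampled to the 5x7 glyph
    grid and matched by Hamming distance; glyphs rendered by the fixture
    module (nearest-neighbour integer scaling) match exactly.  Components
    below ``min_confidence`` map to '*'.
    """

    preprocess = False

    def __init__(self, min_confidence: float = 0.75):
        self.min_confidence = min_confidence
        # templates cropped to their ink bbox: matching must preserve the
        # glyph's aspect ratio ('-' is a 5x1 slab, not a 5x7 block)
        self._templates = {}
        for ch in font.ALPHABET:
            g = font.GLYPHS[ch]
            ys, xs = np.nonzero(g)
            self._templates[ch] = g[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]

    def recognize_glyph(self, glyph: np.ndarray) -> tuple[str, float]:
        ys, xs = np.nonzero(glyph)
        if len(xs) == 0:
            return "", 0.0
        crop = glyph[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
        h, w = crop.shape
        best_ch, best_score = "*", -1.0
        for ch, tpl in self._templates.items():
            th, tw = tpl.shape
            # aspect ratios must be comparable before pixel matching ('o'
            # scales pixel-exactly onto 'O'; only the aspect tells them apart)
            if not (0.75 <= (h / w) / (th / tw) <= 1.33):
                continue
            small = resize(crop.astype(float), (th, tw), order=1, anti_aliasing=False) > 0.5
            score = 1.0 - np.count_nonzero(small != tpl) / tpl.size
            if score > best_score:
                best_ch, best_score = ch, score
        if best_score < self.min_confidence:
            return "*", best_score
        return best_ch, best_score

    def recognize(self, block: np.ndarray) -> tuple[str, float]:
        img = BinaryImage(np.asarray(block, dtype=bool))
        comps = extract_shapes(img)
        if comps:
            # salt specks inside a block are noise, not glyphs
            biggest = max(c.area for c in comps)
            comps = [c for c in comps if c.area >= max(4, 0.08 * biggest)]
        comps.sort(key=lambda s: (s.bbox[0], s.bbox[1]))
        text, confs = [], []
        for comp in comps:
            glyph = np.zeros(img.pixels.shape, dtype=bool)
            glyph[comp.pixels[:, 1], comp.pixels[:, 0]] = True
            ch, conf = self.recognize_glyph(glyph)
            if ch:
                text.append(ch)
                confs.append(conf)
        if not text:
            return "", 0.0
        return "".join(text), float(min(confs))


class TesseractOcr:
    """Adapter for the Tesseract engine (optional dependency, never required)."""

    preprocess = True

    def __init__(self, config: str = "--psm 7"):
        import pytesseract  # deferred: optional extra

        self._engine = pytesseract
        self.config = config

    def recognize(self, block: np.ndarray) -> tuple[str, float]:
        from PIL import Image

        arr = np.where(np.asarray(block, dtype=bool), 0, 255).astype(np.uint8)
        text = self._engine.image_to_string(Image.fromarray(arr), config=self.config)
        text = text.strip()
        return text, 0.9 if text else 0.0


@dataclass
class ParsedAtom:
    kind: str  # "atom" | "abbrev" | "unknown"
    element: str = "*"
    charge: int = 0
    hcount: int = 0
    abbrev: str | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class SymbolGroup:
    shapes: list[Shape]
    roles: list[str] = field(default_factory=list)  # per shape
    texts: dict[str, str] = field(default_factory=dict)  # per role
    confidences: dict[str, float] = field(default_factory=dict)
    parsed: ParsedAtom | None = None

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        boxes = [s.bbox for s in self.shapes]
        return (
            min(b[0] for b in boxes),
            min(b[1] for b in boxes),
            max(b[2] for b in boxes),
            max(b[3] for b in boxes),
        )

    @property
    def center(self) -> tuple[float, float]:
        b = self.bbox
        return ((b[0] + b[2]) / 2.0, (b[1] + b[3]) / 2.0)

    def mainline_shapes(self) -> list[Shape]:
        return [s for s, r in zip(self.shapes, self.roles) if r == "mainline"]


# ---------------------------------------------------------------------------
# shape collection and corrections
# ---------------------------------------------------------------------------


def _shape_skeleton_coords(shape: Shape, skel: BinaryImage) -> np.ndarray:
    m = skel.pixels[shape.pixels[:, 1], shape.pixels[:, 0]]
    return shape.pixels[m]


def _is_thin(skel_coords: np.ndarray) -> bool:
    """Thin-shape test on the thinned pixel set: narrow and elongated."""
    if len(skel_coords) < 2:
        return False
    length, width, _, _ = _geom.oriented_extent(skel_coords)
    return width <= 3.0 and length / max(width, 1.0) >= 4.0


def _bonds_on_component(bonds: list[Bond], comp: Shape, tol: float = 2.0) -> list[int]:
    """Indices of bonds whose source pixels lie (mostly) on the component."""
    if not bonds:
        return []
    tree = cKDTree(comp.pixels.astype(float))
    out = []
    for i, b in enumerate(bonds):
        ref = b.coords.astype(float) if len(b.coords) else np.array([b.end1, b.end2])
        d, _ = tree.query(ref, k=1)
        if (d <= tol).mean() >= 0.8:
            out.append(i)
    return out


def _points_at_symbol(comp_coords: np.ndarray, others: list[Shape], lmed: float) -> bool:
    """Axis extension of a thin shape enters another shape's bbox."""
    length, _, ang, center = _geom.oriented_extent(comp_coords)
    u = (math.cos(math.radians(ang)), math.sin(math.radians(ang)))
    half = length / 2.0
    probes = []
    for sgn in (1.0, -1.0):
        for t in np.linspace(2.0, 0.5 * lmed, 8):
            probes.append((center[0] + sgn * u[0] * (half + t), center[1] + sgn * u[1] * (half + t)))
    for other in others:
        x0, y0, x1, y1 = other.bbox
        for px, py in probes:
            if x0 - 1 <= px <= x1 + 1 and y0 - 1 <= py <= y1 + 1:
                return True
    return False


def correct_bond_false_positives(
    bonds: list[Bond],
    components: list[Shape],
    skel: BinaryImage,
    ocr: OcrBackend,
    lmed: float,
    noise_min_area: int = 4,
    min_glyph_confidence: float = 0.8,
    claim_radius: float = 2.5,
) -> tuple[list[Bond], list[Shape]]:
    """Re-assign ink between bonds and symbols per connected component.

    Returns the corrected bond list and the symbol shapes.  Per component of
    the pre-thinning image: a non-thin, glyph-sized component whose OCR result
    is a valid chemical symbol reclaims its pixels from spurious bonds; a thin
    component stays a bond only when it belongs to a multibond/styled bond or
    points at another symbol-bearing component (otherwise it becomes a
    symbol); everything else keeps its bonds, with leftover ink becoming
    symbol shapes.
    """
    bonds = list(bonds)
    symbol_shapes: list[Shape] = []
    comp_bonds = {
        id(c): _bonds_on_component(bonds, c, tol=claim_radius) for c in components
    }
    removed: set[int] = set()
    # pixel-level claim against the union of all bond sources: a multibond's
    # strokes may straddle two components (inner ring lines touch only each
    # other), so per-bond membership alone must not drive pixel ownership
    all_coords = [b.coords for b in bonds if len(b.coords)]
    all_tree = cKDTree(np.vstack(all_coords).astype(float)) if all_coords else None
    # wedge strokes are triangles up to a quarter bond length wide: their
    # skeleton spine claims a correspondingly wider strip
    wedge_coords = [
        b.coords for b in bonds if b.style == BondStyle.SOLID_WEDGE and len(b.coords)
    ]
    wedge_tree = cKDTree(np.vstack(wedge_coords).astype(float)) if wedge_coords else None
    wedge_radius = claim_radius + 0.13 * lmed

    # component classification needs to know which components look like text
    glyph_like: dict[int, bool] = {}
    for comp in components:
        sk = _shape_skeleton_coords(comp, skel)
        if len(sk) == 0:
            glyph_like[id(comp)] = False
            continue
        if _is_thin(sk):
            glyph_like[id(comp)] = False
            continue
        if max(comp.width, comp.height) > 1.2 * lmed:
            glyph_like[id(comp)] = False  # far larger than any letter
            continue
        bidx = comp_bonds[id(comp)]
        max_bond_len = max((bonds[i].length for i in bidx), default=0.0)
        if max_bond_len >= 0.6 * lmed:
            glyph_like[id(comp)] = False  # structural: carries real bonds
            continue
        if any(bonds[i].style != BondStyle.SOLID or bonds[i].degree > 1 for i in bidx):
            glyph_like[id(comp)] = False
            continue
        mask = np.zeros(skel.pixels.shape, dtype=bool)
        mask[comp.pixels[:, 1], comp.pixels[:, 0]] = True
        _, conf = ocr.recognize(mask)
        glyph_like[id(comp)] = conf >= min_glyph_confidence

    symbolish = [c for c in components if glyph_like[id(c)]]
    for comp in components:
        sk = _shape_skeleton_coords(comp, skel)
        bidx = comp_bonds[id(comp)]
        if glyph_like[id(comp)]:
            removed.update(bidx)  # OCR-validated: reclaim strokes from bonds
            symbol_shapes.append(comp)
            continue
        if len(sk) >= 2 and _is_thin(sk):
            length, _, _, _ = _geom.oriented_extent(sk)
            in_multibond = any(
                bonds[i].degree > 1 or bonds[i].style != BondStyle.SOLID
                for i in bidx
            )
            if in_multibond:
                continue
            if length >= 0.25 * lmed and _points_at_symbol(sk, symbolish, lmed):
                continue
            if length >= 0.7 * lmed:
                continue  # full-length stroke: a bond even in isolation
            removed.update(bidx)
            symbol_shapes.append(comp)
            continue
        # structural component: residual ink not claimed by any bond -> symbols
        claimed = np.zeros(len(comp.pixels), dtype=bool)
        if all_tree is not None:
            d, _ = all_tree.query(comp.pixels.astype(float), k=1)
            claimed = d <= claim_radius
        if wedge_tree is not None:
            d, _ = wedge_tree.query(comp.pixels.astype(float), k=1)
            claimed |= d <= wedge_radius
        residual = comp.pixels[~claimed]
        if len(residual) >= noise_min_area:
            sub = BinaryImage(_coords_to_mask(residual, skel.pixels.shape))
            for s in extract_shapes(sub):
                if s.area >= noise_min_area:
                    symbol_shapes.append(s)
    bonds = [b for i, b in enumerate(bonds) if i not in removed]
    symbol_shapes.sort(key=lambda s: (s.bbox, tuple(s.pixels[0])))
    return bonds, symbol_shapes


def _coords_to_mask(coords: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    if len(coords):
        m[coords[:, 1], coords[:, 0]] = True
    return m


def collect_symbol_shapes(
    components: list[Shape],
    bonds: list[Bond],
    skel: BinaryImage,
    lmed: float,
    noise_min_area: int = 4,
    claim_radius: float = 2.5,
) -> list[Shape]:
    """Residual (non-bond) shapes above the noise floor, geometrically only.

    This is the OCR-free subset of :func:`correct_bond_false_positives`; the
    pipeline uses the latter, which also repairs glyphs chopped by spurious
    bond detections.
    """
    out: list[Shape] = []
    for comp in components:
        bidx = _bonds_on_component(bonds, comp)
        if not bidx:
            if comp.area >= noise_min_area:
                out.append(comp)
            continue
        coords_list = [bonds[i].coords for i in bidx if len(bonds[i].coords)]
        claimed = np.zeros(len(comp.pixels), dtype=bool)
        if coords_list:
            tree = cKDTree(np.vstack(coords_list).astype(float))
            d, _ = tree.query(comp.pixels.astype(float), k=1)
            claimed = d <= claim_radius
        residual = comp.pixels[~claimed]
        if len(residual) >= noise_min_area:
            sub = BinaryImage(_coords_to_mask(residual, skel.pixels.shape))
            out.extend(s for s in extract_shapes(sub) if s.area >= noise_min_area)
    out.sort(key=lambda s: (s.bbox, tuple(s.pixels[0])))
    return out


def correct_symbol_false_positives(
    symbol_shapes: list[Shape],
    bonds: list[Bond],
    skel: BinaryImage,
    lmed: float,
    orient_tol: float = 15.0,
) -> tuple[list[Shape], list[Bond]]:
    """Restore oblique thin symbol shapes as solid bonds.

    Solid line bonds are the only style that masquerades as a symbol; letters
    with straight strokes (l, I) are axis-aligned, so thin shapes tilted more
    than ``orient_tol`` away from both axes become degree-1 bonds spanning
    their extreme pixels.
    """
    bonds = list(bonds)
    kept: list[Shape] = []
    for s in symbol_shapes:
        sk = _shape_skeleton_coords(s, skel)
        if len(sk) < 2:
            kept.append(s)
            continue
        length, width, ang, center = _geom.oriented_extent(sk)
        off_axis = min(_geom.angle_diff(ang, 0.0), _geom.angle_diff(ang, 90.0))
        if not (_is_thin(sk) and off_axis > orient_tol and length >= 0.25 * lmed):
            kept.append(s)
            continue
        u = (math.cos(math.radians(ang)), math.sin(math.radians(ang)))
        proj = (sk[:, 0] - center[0]) * u[0] + (sk[:, 1] - center[1]) * u[1]
        i1, i2 = int(np.argmin(proj)), int(np.argmax(proj))
        e1 = (float(sk[i1, 0]), float(sk[i1, 1]))
        e2 = (float(sk[i2, 0]), float(sk[i2, 1]))
        bonds.append(Bond(style=BondStyle.SOLID, degree=1, end1=e1, end2=e2, coords=sk))
    bonds.sort(key=lambda b: (b.end1, b.end2, b.degree))
    return kept, bonds


# ---------------------------------------------------------------------------
# grouping, role classification, OCR, parsing
# ---------------------------------------------------------------------------


def group_nearby(shapes: list[Shape], gap_factor: float = 0.6) -> list[SymbolGroup]:
    """Single-linkage clustering of symbol shapes into symbol groups.

    The linkage gap for a pair is ``gap_factor`` times the smaller of the two
    shapes' larger bbox dimensions, so letters of one label group together
    while labels of different atoms (a bond length apart) stay separate and
    oversized noise shapes do not skew the scale.
    """
    if not shapes:
        return []
    ds = DisjointSet(range(len(shapes)))
    dims = [max(s.width, s.height) for s in shapes]
    for i in range(len(shapes)):
        for j in range(i + 1, len(shapes)):
            gap = max(3.0, gap_factor * min(dims[i], dims[j]))
            if _bbox_gap(shapes[i].bbox, shapes[j].bbox) <= gap:
                ds.merge(i, j)
    groups = []
    for idx_set in sorted(ds.subsets(), key=lambda g: min(g)):
        members = [shapes[i] for i in sorted(idx_set)]
        members.sort(key=lambda s: (s.bbox[0], s.bbox[1]))
        groups.append(SymbolGroup(shapes=members))
    groups.sort(key=lambda g: g.bbox)
    return groups


def _bbox_gap(a, b) -> float:
    dx = max(0, max(a[0], b[0]) - min(a[2], b[2]))
    dy = max(0, max(a[1], b[1]) - min(a[3], b[3]))
    return math.hypot(dx, dy)


def classify_roles(group: SymbolGroup) -> SymbolGroup:
    """Assign mainline/superscript/subscript roles by relative size and height.

    Shapes at least 70% of the tallest shape are mainline; smaller shapes are
    superscript when raised above the mainline vertical center, subscript when
    lowered.
    """
    if not group.shapes:
        group.roles = []
        return group
    hmax = max(s.height for s in group.shapes)
    mainline = [s.height >= 0.7 * hmax for s in group.shapes]
    centers = [((s.bbox[1] + s.bbox[3]) / 2.0) for s in group.shapes]
    main_c = float(np.mean([c for c, m in zip(centers, mainline) if m]))
    roles = []
    for s, m, c in zip(group.shapes, mainline, centers):
        if m:
            roles.append("mainline")
        elif c < main_c:
            roles.append("superscript")
        else:
            roles.append("subscript")
    group.roles = roles
    return group


def ocr_blocks(group: SymbolGroup, backend: OcrBackend, img: BinaryImage) -> SymbolGroup:
    """Run OCR per script role, submitting consecutive same-role shapes as one
    block.  Optional preprocessing (upscaling to a fixed glyph height, light
    smoothing, 1-px dilation) is applied for backends that want it."""
    if not group.roles:
        classify_roles(group)
    texts: dict[str, str] = {}
    confs: dict[str, float] = {}
    for role in ("mainline", "superscript", "subscript"):
        members = [s for s, r in zip(group.shapes, group.roles) if r == role]
        if not members:
            continue
        x0 = min(s.bbox[0] for s in members)
        y0 = min(s.bbox[1] for s in members)
        x1 = max(s.bbox[2] for s in members)
        y1 = max(s.bbox[3] for s in members)
        block = np.zeros((y1 - y0 + 1, x1 - x0 + 1), dtype=bool)
        for s in members:
            block[s.pixels[:, 1] - y0, s.pixels[:, 0] - x0] = True
        if getattr(backend, "preprocess", False):
            block = _preprocess_block(block)
        try:
            text, conf = backend.recognize(block)
        except Exception:  # backend failure degrades, never crashes
            log.warning("OCR backend failed on a %s block", role)
            text, conf = "", 0.0
        texts[role] = text
        confs[role] = conf
    group.texts = texts
    group.confidences = confs
    return group


def _preprocess_block(block: np.ndarray, target_height: int = 32) -> np.ndarray:
    from scipy.ndimage import binary_dilation, gaussian_filter

    h = block.shape[0]
    if h < target_height:
        f = int(math.ceil(target_height / h))
        block = np.kron(block, np.ones((f, f), dtype=bool))
    sm = gaussian_filter(block.astype(float), 0.5) > 0.4
    return binary_dilation(sm)


def load_abbreviations(path: str | None = None) -> dict[str, str]:
    """Load the superatom abbreviation table (ABBREV<TAB>SMILES-with-star).

    Without ``path`` the dictionary shipped with the package is used.
    """
    if path is None:
        from importlib.resources import files

        text = files("ocsr").joinpath("data/abbreviations.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, smiles = line.split("\t")
        table[key] = smiles
    return table


_TOKEN_RE = re.compile(r"[A-Z][a-z]?|.")


def _element_tokens(text: str) -> list[str] | None:
    """Tokenize mainline text into element symbols (2-letter priority)."""
    tokens = []
    i = 0
    while i < len(text):
        if i + 1 < len(text) and text[i : i + 2] in ELEMENTS:
            tokens.append(text[i : i + 2])
            i += 2
        elif text[i] in ELEMENTS:
            tokens.append(text[i])
            i += 1
        elif text[i] in "()[]":
            i += 1  # grouping brackets carry no atom
        else:
            return None
    return tokens


def _parse_charge(sup: str) -> tuple[int, list[str]]:
    sup = sup.replace("*", "")  # unrecognized specks in the block are noise
    if not sup:
        return 0, []
    m = re.fullmatch(r"(\d*)([+-])|([+-])(\d*)", sup)
    if not m:
        return 0, [f"malformed charge {sup!r}"]
    num = m.group(1) or m.group(4) or "1"
    sign = m.group(2) or m.group(3)
    mag = int(num)
    if mag > 4:
        return 0, [f"charge magnitude {mag} > 4"]
    return (mag if sign == "+" else -mag), []


def parse_group(group: SymbolGroup, abbreviations: dict | None = None) -> SymbolGroup:
    """Parse OCR texts into an atom or an abbreviation reference.

    Mainline text with at most one non-hydrogen element becomes a single atom
    (hydrogens counted from the subscript, charge from the superscript);
    anything else is looked up in the abbreviation dictionary; failing that
    the group becomes an unknown atom '*'.
    """
    main = (group.texts or {}).get("mainline", "")
    sup = (group.texts or {}).get("superscript", "")
    sub = (group.texts or {}).get("subscript", "")
    abbreviations = abbreviations if abbreviations is not None else {}
    flags: list[str] = []
    charge, charge_flags = _parse_charge(sup)
    flags += charge_flags

    tokens = _element_tokens(main) if main else None
    if tokens and "*" not in main:
        heavy = [t for t in tokens if t != "H"]
        if len(heavy) <= 1:
            hcount = 0
            if "H" in tokens:
                digits = re.search(r"\d+", sub)
                hcount = int(digits.group()) if digits else 1
            element = heavy[0] if heavy else "H"
            group.parsed = ParsedAtom(
                kind="atom", element=element, charge=charge, hcount=hcount, flags=flags
            )
            return group
    if main in abbreviations:
        group.parsed = ParsedAtom(kind="abbrev", element=main, abbrev=main,
                                  charge=charge, flags=flags)
        return group
    flags.append(f"unresolvable symbol text {main!r}")
    group.parsed = ParsedAtom(kind="unknown", element="*", charge=charge, flags=flags)
    return group
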