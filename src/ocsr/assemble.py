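"""Molecule graph assembly, Molfile V2000 export, and the end-to-end pipeline.

The resolved atoms and bonds become a graph (atoms as nodes, bonds as edges);
caption noise tends to produce small disconnected fragments, so the largest
connected component is kept.  Abbreviation pseudo-atoms are substituted with
their dictionary substructures, explicit hydrogen counts are expanded into H
atoms, and the result is serialized as an MDL Molfile V2000 (y axis flipped
at export; coordinates normalized to 1.5 units per median bond length).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from . import _geom, fmlines, raster, resolve as resolve_mod, symbols as symbols_mod
from . import bonds as bonds_mod
from .bonds import BondStyle
from .config import Config
from .errors import BlankImageError, EmptyGraphError, MolfileError, UnreadableImageError
from .raster import BinaryImage
from .symbols import OcrBackend, StubOcr

log = logging.getLogger(__name__)

Point = tuple[float, float]


@dataclass
class Atom:
    element: str
    charge: int = 0
    hcount: int = 0
    pos: Point = (0.0, 0.0)
    is_abbrev: bool = False


@dataclass
class BondEdge:
    i: int
    j: int
    order: int = 1
    aromatic: bool = False
    style: str = "solid_line"


@dataclass
class MoleculeGraph:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[BondEdge] = field(default_factory=list)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, a in enumerate(self.atoms):
            g.add_node(i, element=a.element, charge=a.charge, hcount=a.hcount)
        for b in self.bonds:
            g.add_edge(b.i, b.j, order=b.order, aromatic=b.aromatic)
        return g


def connect(resolved: resolve_mod.ResolvedStructure) -> MoleculeGraph:
    """Atoms + resolved bonds -> graph; self-loops and dangling bonds dropped."""
    atoms = [
        Atom(
            element=a.parsed.element,
            charge=a.parsed.charge,
            hcount=a.parsed.hcount,
            pos=a.center,
            is_abbrev=a.parsed.kind == "abbrev",
        )
        for a in resolved.atoms
    ]
    edges: dict[tuple[int, int], BondEdge] = {}
    for b in resolved.bonds:
        if b.atom1 is None or b.atom2 is None:
            log.warning("bond with unresolved ending dropped")
            continue
        if b.atom1 == b.atom2:
            log.warning("bond with both endings in one atom dropped")
            continue
        key = (min(b.atom1, b.atom2), max(b.atom1, b.atom2))
        aromatic = b.style == BondStyle.AROMATIC
        if key in edges:
            prev = edges[key]
            edges[key] = replace(
                prev,
                order=min(3, prev.order + b.degree),
                aromatic=prev.aromatic or aromatic,
            )
        else:
            edges[key] = BondEdge(
                i=key[0], j=key[1], order=b.degree, aromatic=aromatic, style=b.style.value
            )
    return MoleculeGraph(atoms=atoms, bonds=sorted(edges.values(), key=lambda e: (e.i, e.j)))


def largest_component(graph: MoleculeGraph) -> MoleculeGraph:
    """Keep the component with most atoms (ties: most bonds, lowest index)."""
    if not graph.atoms:
        raise EmptyGraphError("nothing recognized")
    g = graph.to_networkx()
    comps = list(nx.connected_components(g))
    def keyf(c):
        nodes = sorted(c)
        nbonds = sum(1 for b in graph.bonds if b.i in c and b.j in c)
        return (-len(nodes), -nbonds, nodes[0])
    best = sorted(comps, key=keyf)[0]
    keep = sorted(best)
    remap = {old: new for new, old in enumerate(keep)}
    atoms = [graph.atoms[i] for i in keep]
    bonds = [
        replace(b, i=remap[b.i], j=remap[b.j])
        for b in graph.bonds
        if b.i in remap and b.j in remap
    ]
    return MoleculeGraph(atoms=atoms, bonds=sorted(bonds, key=lambda e: (e.i, e.j)))


# ---------------------------------------------------------------------------
# abbreviation expansion
# ---------------------------------------------------------------------------

_FRAGMENT_CACHE: dict[str, tuple[list[Atom], list[BondEdge], int]] = {}


def _fragment_from_smiles(smiles: str):
    """Parse a dictionary SMILES (with * attachment) into atoms/bonds and the
    attachment atom index."""
    if smiles in _FRAGMENT_CACHE:
        return _FRAGMENT_CACHE[smiles]
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"bad dictionary SMILES {smiles!r}")
    Chem.Kekulize(mol, clearAromaticFlags=True)
    star = next(a for a in mol.GetAtoms() if a.GetSymbol() == "*")
    neighbors = star.GetNeighbors()
    if len(neighbors) != 1:
        raise ValueError(f"dictionary entry {smiles!r} must have one attachment")
    attach_old = neighbors[0].GetIdx()
    keep = [a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() != star.GetIdx()]
    remap = {old: new for new, old in enumerate(keep)}
    atoms = []
    for old in keep:
        a = mol.GetAtomWithIdx(old)
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                charge=a.GetFormalCharge(),
                hcount=a.GetTotalNumHs(),
            )
        )
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if star.GetIdx() in (i, j):
            continue
        order = int(b.GetBondTypeAsDouble())
        bonds.append(BondEdge(i=remap[min(i, j)], j=remap[max(i, j)], order=order))
    out = (atoms, bonds, remap[attach_old])
    _FRAGMENT_CACHE[smiles] = out
    return out


def expand_abbreviations(
    graph: MoleculeGraph, dictionary: dict[str, str] | None = None
) -> MoleculeGraph:
    """Substitute abbreviation pseudo-atoms with their substructures.

    The attachment atom bonds to the pseudo-atom's former neighbour; inserted
    atoms are laid out on a small deterministic spiral near the pseudo-atom
    position.  Pseudo-atoms with other than one neighbour are flagged and left
    in place as '*'.
    """
    if dictionary is None:
        dictionary = symbols_mod.load_abbreviations()
    atoms = list(graph.atoms)
    bonds = list(graph.bonds)
    for idx in range(len(atoms)):
        a = atoms[idx]
        if not a.is_abbrev:
            continue
        neighbors = [b for b in bonds if idx in (b.i, b.j)]
        if a.element not in dictionary:
            log.warning("unknown abbreviation %r left as pseudo-atom", a.element)
            atoms[idx] = replace(a, element="*", is_abbrev=False)
            continue
        if len(neighbors) != 1:
            log.warning(
                "abbreviation %r with %d neighbours not expanded", a.element, len(neighbors)
            )
            atoms[idx] = replace(a, element="*", is_abbrev=False)
            continue
        frag_atoms, frag_bonds, attach = _fragment_from_smiles(dictionary[a.element])
        base = len(atoms)
        for k, fa in enumerate(frag_atoms):
            ang = 2.399963 * k  # golden-angle spiral: deterministic, non-overlapping
            r = 8.0 * (1 + k // 6)
            atoms.append(
                replace(fa, pos=(a.pos[0] + r * math.cos(ang), a.pos[1] + r * math.sin(ang)))
            )
        for fb in frag_bonds:
            bonds.append(replace(fb, i=base + fb.i, j=base + fb.j))
        nb = neighbors[0]
        other = nb.j if nb.i == idx else nb.i
        bonds = [b for b in bonds if b is not nb]
        bonds.append(BondEdge(i=min(other, base + attach), j=max(other, base + attach),
                              order=nb.order))
        atoms[idx] = None  # removed below
    remap = {}
    out_atoms = []
    for i, a in enumerate(atoms):
        if a is not None:
            remap[i] = len(out_atoms)
            out_atoms.append(a)
    out_bonds = [
        replace(b, i=remap[min(b.i, b.j)], j=remap[max(b.i, b.j)])
        for b in bonds
        if b.i in remap and b.j in remap
    ]
    return MoleculeGraph(atoms=out_atoms, bonds=sorted(out_bonds, key=lambda e: (e.i, e.j)))


def add_explicit_hydrogens(graph: MoleculeGraph) -> MoleculeGraph:
    """Expand per-atom hydrogen counts into explicit H atoms.

    Explicit H emission survives more parsers than valence fields and stays
    faithful to what the OCR actually read."""
    atoms = list(graph.atoms)
    bonds = list(graph.bonds)
    for idx in range(len(graph.atoms)):
        a = graph.atoms[idx]
        for k in range(a.hcount):
            ang = math.pi / 4 + k * math.pi / 2
            atoms.append(
                Atom(element="H", pos=(a.pos[0] + 10 * math.cos(ang), a.pos[1] + 10 * math.sin(ang)))
            )
            bonds.append(BondEdge(i=idx, j=len(atoms) - 1, order=1))
        if a.hcount:
            atoms[idx] = replace(a, hcount=0)
    return MoleculeGraph(atoms=atoms, bonds=bonds)


# ---------------------------------------------------------------------------
# Molfile V2000
# ---------------------------------------------------------------------------


def write_molfile(graph: MoleculeGraph, image_height: float) -> str:
    """Serialize as MDL Molfile V2000 (byte-stable for a fixed graph).

    Pixel coordinates are scaled so the median bond length is 1.5 units and
    the y axis is flipped (Molfile y grows upward).  Aromatic ring bonds are
    written as bond type 4; charges go to ``M  CHG`` lines.
    """
    if not graph.atoms:
        raise EmptyGraphError("empty graph cannot be serialized")
    if len(graph.atoms) > 999 or len(graph.bonds) > 999:
        raise MolfileError("V2000 limit: more than 999 atoms or bonds")
    if graph.bonds:
        med = float(
            np.median(
                [
                    _geom.dist(graph.atoms[b.i].pos, graph.atoms[b.j].pos)
                    for b in graph.bonds
                ]
            )
        )
    else:
        med = 40.0
    s = 1.5 / med if med > 0 else 1.0
    lines = ["", "  ocsr   2D", ""]
    lines.append(
        f"{len(graph.atoms):3d}{len(graph.bonds):3d}  0  0  0  0  0  0  0  0999 V2000"
    )
    for a in graph.atoms:
        x = a.pos[0] * s
        y = (image_height - a.pos[1]) * s
        lines.append(f"{x:10.4f}{y:10.4f}{0.0:10.4f} {a.element:<3} 0  0  0  0  0  0  0  0  0  0  0  0")
    for b in graph.bonds:
        order = 4 if b.aromatic else b.order
        lines.append(f"{b.i + 1:3d}{b.j + 1:3d}{order:3d}  0  0  0  0")
    charged = [(i + 1, a.charge) for i, a in enumerate(graph.atoms) if a.charge]
    for k in range(0, len(charged), 8):
        chunk = charged[k : k + 8]
        rec = f"M  CHG{len(chunk):3d}"
        for idx, chg in chunk:
            rec += f"{idx:4d}{chg:4d}"
        lines.append(rec)
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def read_molfile(text: str) -> MoleculeGraph:
    """Parse a V2000 Molfile written by :func:`write_molfile`."""
    lines = text.splitlines()
    counts = lines[3]
    na, nb = int(counts[0:3]), int(counts[3:6])
    atoms = []
    for k in range(na):
        ln = lines[4 + k]
        x, y = float(ln[0:10]), float(ln[10:20])
        el = ln[31:34].strip()
        atoms.append(Atom(element=el, pos=(x, y)))
    bonds = []
    for k in range(nb):
        ln = lines[4 + na + k]
        i, j, order = int(ln[0:3]) - 1, int(ln[3:6]) - 1, int(ln[6:9])
        aromatic = order == 4
        bonds.append(
            BondEdge(i=min(i, j), j=max(i, j), order=1 if aromatic else order, aromatic=aromatic)
        )
    for ln in lines[4 + na + nb :]:
        if ln.startswith("M  CHG"):
            n = int(ln[6:9])
            for k in range(n):
                idx = int(ln[9 + 8 * k : 13 + 8 * k]) - 1
                chg = int(ln[13 + 8 * k : 17 + 8 * k])
                atoms[idx] = replace(atoms[idx], charge=chg)
        if ln.startswith("M  END"):
            break
    return MoleculeGraph(atoms=atoms, bonds=sorted(bonds, key=lambda e: (e.i, e.j)))


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineDebug:
    """Optional bag of intermediate artifacts for inspection."""

    work: BinaryImage | None = None
    skeleton: BinaryImage | None = None
    circles: list = field(default_factory=list)
    lines: list = field(default_factory=list)
    bonds: list = field(default_factory=list)
    symbol_shapes: list = field(default_factory=list)
    groups: list = field(default_factory=list)
    network: object = None
    assignment: object = None
    resolved: object = None
    graph: MoleculeGraph | None = None
    lmed: float = 0.0


def _load_image(source) -> np.ndarray:
    if isinstance(source, np.ndarray):
        return source
    if isinstance(source, BinaryImage):
        return np.where(source.pixels, 0, 255).astype(np.uint8)
    from PIL import Image, UnidentifiedImageError

    try:
        with Image.open(source) as im:
            return np.array(im.convert("L"))
    except (OSError, UnidentifiedImageError) as exc:
        raise UnreadableImageError(f"cannot read image {source!r}: {exc}") from exc


def recognize_graph(
    source,
    config: Config | None = None,
    ocr: OcrBackend | None = None,
    debug: PipelineDebug | None = None,
) -> tuple[MoleculeGraph, float]:
    """Full recognition pipeline; returns the molecule graph (hydrogen counts
    still implicit, abbreviations expanded) and the working image height."""
    cfg = config or Config()
    ocr = ocr or StubOcr()
    gray = _load_image(source)
    binary = raster.binarize(gray, cfg.binarize_threshold)
    if binary.ink_count == 0:
        raise BlankImageError("blank image")
    work, scale = raster.trim_pad_upscale(binary, pad=cfg.pad, min_dim=cfg.min_dim)
    skel = raster.thin(work)
    stroke_w = work.ink_count / max(skel.ink_count, 1)

    # radius bounds scale with the preprocessing upscale so letter-sized
    # glyph arcs (O, S) stay below the aromatic-circle search range
    circles = raster.detect_circles(
        skel,
        radius_range=(cfg.circle_rmin * scale, cfg.circle_rmax * scale),
        min_arc=math.radians(cfg.circle_min_arc_deg),
    )
    skel_nc = skel
    work_nc = work
    for c in circles:
        skel_nc = raster.mask_pixels(
            skel_nc, raster.circle_ring_coords(skel_nc, c, radial_tol=3.5)
        )
        work_nc = raster.mask_pixels(
            work_nc,
            raster.circle_ring_coords(work_nc, c, radial_tol=stroke_w / 2.0 + 2.5),
        )

    lines = fmlines.fragment_merging(
        skel_nc,
        rho_res=cfg.hough_rho_res,
        theta_res=cfg.hough_theta_res,
        min_votes=cfg.hough_min_votes,
        angle_threshold=cfg.fm_angle_threshold,
        dist_threshold=cfg.fm_dist_threshold,
    )
    lmed = bonds_mod.median_line_length(lines)
    if lmed == 0:
        lmed = 40.0 * scale

    bond_list = bonds_mod.group_multibonds(
        lines,
        lmed,
        angle_tol=cfg.multibond_angle_tol,
        lateral_frac=cfg.multibond_lateral_frac,
        min_len_ratio=cfg.multibond_len_ratio,
        min_overlap=cfg.multibond_overlap,
    )
    bond_list = bonds_mod.split_at_intersections(bond_list, lmed)
    bond_list = bonds_mod.split_collinear(bond_list, lmed)
    bond_list = bonds_mod.detect_solid_wedges(
        bond_list,
        work_nc,
        num_samples=cfg.wedge_num_samples,
        center_fraction=cfg.wedge_center_fraction,
        min_max_width=max(cfg.wedge_min_max_width, int(2.0 * stroke_w)),
        min_wedge_ratio=cfg.wedge_min_ratio,
        min_length=0.5 * lmed,
    )
    # candidate shapes for dash/wavy detection: thinned components that remain
    # once confidently long solid bonds are masked.  Masking uses a corridor
    # around each bond segment (recorded pixels can miss wobbly junction runs)
    from scipy.ndimage import distance_transform_edt

    ink_dist = distance_transform_edt(~work_nc.pixels)

    def _covered(b) -> bool:
        # lines claimed on a curved squiggle cross empty interior or hop
        # between arcs; only lines hugging continuous ink may mask pixels
        thr = max(2.0, stroke_w / 2.0 + 1.5)
        for p1, p2 in b.segments:
            for k in range(16):
                t = (k + 0.5) / 16
                x = int(round(p1[0] + t * (p2[0] - p1[0])))
                y = int(round(p1[1] + t * (p2[1] - p1[1])))
                if not (0 <= x < work_nc.width and 0 <= y < work_nc.height):
                    return False
                if ink_dist[y, x] > thr:
                    return False
        return True

    long_segs = [
        seg
        for b in bond_list
        if b.style in (BondStyle.SOLID, BondStyle.SOLID_WEDGE)
        and b.length >= 0.5 * lmed
        and _covered(b)
        for seg in b.segments
    ]
    skel_residual = skel_nc
    if long_segs:
        coords = skel_nc.ink_coords().astype(float)
        claimed = np.zeros(len(coords), dtype=bool)
        for (p1, p2) in long_segs:
            d = np.array(p2) - np.array(p1)
            n2 = float(d @ d)
            if n2 == 0:
                continue
            t = np.clip(((coords - np.array(p1)) @ d) / n2, 0.0, 1.0)
            foot = np.array(p1)[None, :] + t[:, None] * d[None, :]
            claimed |= np.hypot(*(coords - foot).T) <= 2.5
        # pixels also covered by short detections (dash strokes, squiggle
        # pieces) are protected: a long line occasionally overreaches into an
        # adjacent dash/wavy shape at a junction
        short_coords = [
            b.coords
            for b in bond_list
            if b.style == BondStyle.SOLID and b.length < 0.5 * lmed and len(b.coords)
        ]
        if short_coords:
            from scipy.spatial import cKDTree

            tree = cKDTree(np.vstack(short_coords).astype(float))
            d_short, _ = tree.query(coords, k=1)
            claimed &= d_short > 1.5
        skel_residual = raster.mask_pixels(skel_nc, coords[claimed].astype(int))
    residual_shapes = raster.extract_shapes(skel_residual)
    bond_list, residual_shapes = bonds_mod.detect_dashed(
        bond_list,
        residual_shapes,
        residual_shapes,
        lmed,
        max_angle=cfg.dashed_max_angle,
        min_group=cfg.dashed_min_group,
    )
    def _reads_as_text(cluster) -> bool:
        x0, y0, x1, y1 = cluster.bbox
        block = work_nc.pixels[y0 : y1 + 1, x0 : x1 + 1]
        try:
            text, conf = ocr.recognize(block)
        except Exception:
            return False
        return conf >= 0.85 and any(c.isalnum() for c in text)

    bond_list, residual_shapes = bonds_mod.detect_wavy(
        bond_list,
        residual_shapes,
        lmed,
        min_num_circles=cfg.wavy_min_circles,
        veto=_reads_as_text,
    )
    bond_list = bonds_mod.mark_aromatic_rings(bond_list, circles, lmed)

    components = raster.extract_shapes(work_nc)
    claim_radius = max(2.5, stroke_w / 2.0 + 1.5)
    bond_list, symbol_shapes = symbols_mod.correct_bond_false_positives(
        bond_list,
        components,
        skel_nc,
        ocr,
        lmed,
        noise_min_area=cfg.noise_min_area * scale,
        claim_radius=claim_radius,
    )
    symbol_shapes, bond_list = symbols_mod.correct_symbol_false_positives(
        symbol_shapes, bond_list, skel_nc, lmed, orient_tol=cfg.orient_tol
    )
    symbol_shapes = [s for s in symbol_shapes if s.area >= cfg.noise_min_area * scale]

    abbrevs = symbols_mod.load_abbreviations()
    groups = symbols_mod.group_nearby(symbol_shapes, gap_factor=cfg.symbol_gap_factor)
    for g in groups:
        symbols_mod.classify_roles(g)
        symbols_mod.ocr_blocks(g, ocr, work_nc)
        symbols_mod.parse_group(g, abbrevs)
    # groups that neither parse nor read confidently are leftover noise, not
    # atoms; keeping them would graft unknown atoms onto the graph
    def _is_noise_group(g):
        if g.parsed.kind != "unknown":
            return False
        text = g.texts.get("mainline", "")
        if not any(c.isalnum() for c in text):
            return True  # punctuation-only reads are never atoms
        return g.confidences.get("mainline", 0.0) < 0.8

    groups = [g for g in groups if not _is_noise_group(g)]

    slmed = 10.0
    main_sizes = [
        max(s.width, s.height) for g in groups for s in g.mainline_shapes()
    ]
    if main_sizes:
        slmed = float(np.median(main_sizes))

    atom_cands = resolve_mod.make_atom_candidates(bond_list, groups, lmed, slmed)
    bond_cands = resolve_mod.make_bond_candidates(bond_list)
    net = resolve_mod.build_network(
        atom_cands, bond_cands, work_nc, lmed, n_coverage_samples=cfg.coverage_samples
    )
    assignment = resolve_mod.map_inference(
        net, enum_limit=cfg.enum_limit, bp_sweeps=cfg.bp_sweeps, damping=cfg.bp_damping
    )
    resolved = resolve_mod.resolve_candidates(assignment, atom_cands, bond_cands)

    graph = connect(resolved)
    graph = largest_component(graph)
    graph = expand_abbreviations(graph, abbrevs)

    if debug is not None:
        debug.work = work
        debug.skeleton = skel
        debug.circles = circles
        debug.lines = lines
        debug.bonds = bond_list
        debug.symbol_shapes = symbol_shapes
        debug.groups = groups
        debug.network = net
        debug.assignment = assignment
        debug.resolved = resolved
        debug.graph = graph
        debug.lmed = lmed
    return graph, float(work.height)


def recognize(
    source,
    config: Config | None = None,
    ocr: OcrBackend | None = None,
    debug: PipelineDebug | None = None,
) -> str:
    """Recognize a structure image and return its Molfile text."""
    graph, height = recognize_graph(source, config=config, ocr=ocr, debug=debug)
    graph = add_explicit_hydrogens(graph)
    return write_molfile(graph, height)
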