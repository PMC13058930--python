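"""Atom/bond candidate creation and Markov-network ambiguity resolution.

Component extraction yields bonds (two ending points each) and symbol groups
(bounding boxes plus OCR results).  Mapping them onto a molecule graph is
ambiguous: at a furcation a few pixels of ending jitter decide which bonds
share an atom, and duplicate or spurious detections must be discarded.  The
candidate mechanism makes those decisions probabilistic:

* every bond ending spawns an *atom candidate* with a circular bounding area
  of radius ``rb = min(l_bond, l_med) / 4``;
* every terminal mainline symbol of a group spawns an atom candidate with a
  square bounding area of side ``sl_b = 1.5 * max(sl_sym, sl_med)``;
* every detected bond spawns a *bond candidate* with the same endings.

A Markov network over boolean existence and pairwise merge variables is built
from geometric rules (existence potentials of 0.9 when a candidate is
supported; distance-decaying merge likelihoods), MAP inference selects the
most probable joint state, and candidates are merged by growing transitive
closure into final atoms and bonds.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import DisjointSet
from scipy.ndimage import distance_transform_edt

from . import _geom
from .bonds import Bond, BondStyle
from .raster import BinaryImage
from .symbols import ParsedAtom, SymbolGroup

log = logging.getLogger(__name__)

Point = tuple[float, float]


# ---------------------------------------------------------------------------
# candidates
# ---------------------------------------------------------------------------


@dataclass
class AtomCandidate:
    origin: str  # "bond" | "symbol"
    center: Point
    rb: float | None = None  # bounding-circle radius (bond-ending origin)
    slb: float | None = None  # bounding-square side (symbol origin)
    bond_index: int | None = None
    end_index: int | None = None  # 0 or 1
    carrier: tuple[Point, Point] | None = None  # infinite line of the bond
    group: SymbolGroup | None = None

    def overlaps(self, other: "AtomCandidate") -> bool:
        """Bounding-area intersection test (circle/circle, circle/square,
        square/square)."""
        a, b = self, other
        if a.origin == "bond" and b.origin == "bond":
            return _geom.dist(a.center, b.center) <= a.rb + b.rb
        if a.origin == "symbol" and b.origin == "symbol":
            ha, hb = a.slb / 2, b.slb / 2
            return (
                abs(a.center[0] - b.center[0]) <= ha + hb
                and abs(a.center[1] - b.center[1]) <= ha + hb
            )
        circ, sq = (a, b) if a.origin == "bond" else (b, a)
        h = sq.slb / 2
        cx = min(max(circ.center[0], sq.center[0] - h), sq.center[0] + h)
        cy = min(max(circ.center[1], sq.center[1] - h), sq.center[1] + h)
        return _geom.dist(circ.center, (cx, cy)) <= circ.rb


@dataclass
class BondCandidate:
    end1: Point
    end2: Point
    degree: int
    style: BondStyle
    bond_index: int
    segments: tuple[tuple[Point, Point], ...] = ()

    @property
    def center(self) -> Point:
        return ((self.end1[0] + self.end2[0]) / 2.0, (self.end1[1] + self.end2[1]) / 2.0)

    @property
    def length(self) -> float:
        return _geom.dist(self.end1, self.end2)


def make_atom_candidates(
    bonds: list[Bond],
    symbol_groups: list[SymbolGroup],
    lmed: float,
    slmed: float,
) -> list[AtomCandidate]:
    """Create atom candidates at bond endings and terminal mainline symbols."""
    cands: list[AtomCandidate] = []
    for bi, bond in enumerate(bonds):
        rb = min(bond.length, lmed) / 4.0
        for ei, end in enumerate((bond.end1, bond.end2)):
            cands.append(
                AtomCandidate(
                    origin="bond",
                    center=(float(end[0]), float(end[1])),
                    rb=rb,
                    bond_index=bi,
                    end_index=ei,
                    carrier=(bond.end1, bond.end2),
                )
            )
    for group in symbol_groups:
        mains = group.mainline_shapes()
        if not mains:
            continue
        boxes = [s.bbox for s in mains]
        xs = [(b[0] + b[2]) / 2.0 for b in boxes]
        ys = [(b[1] + b[3]) / 2.0 for b in boxes]
        gb = group.bbox
        horizontal = (gb[2] - gb[0]) >= (gb[3] - gb[1])
        order = np.argsort(xs if horizontal else ys)
        terminals = {int(order[0]), int(order[-1])}
        for k in sorted(terminals):
            s = mains[k]
            slsym = float(max(s.width, s.height))
            slb = 1.5 * max(slsym, slmed)
            cands.append(
                AtomCandidate(
                    origin="symbol",
                    center=(xs[k], ys[k]),
                    slb=slb,
                    group=group,
                )
            )
    return cands


def make_bond_candidates(bonds: list[Bond]) -> list[BondCandidate]:
    return [
        BondCandidate(
            end1=(float(b.end1[0]), float(b.end1[1])),
            end2=(float(b.end2[0]), float(b.end2[1])),
            degree=b.degree,
            style=b.style,
            bond_index=i,
            segments=b.segments,
        )
        for i, b in enumerate(bonds)
    ]


# ---------------------------------------------------------------------------
# merge likelihoods
# ---------------------------------------------------------------------------


def candidates_interact(a1: AtomCandidate, a2: AtomCandidate, lmed: float) -> bool:
    """Can two atom candidates possibly be one atom (merge node creation)?

    Bond-ending pairs interact when their bounding circles overlap.  For a
    bond-ending/symbol pair the interaction region is the high-likelihood
    band of the distant-connection rule (d <= S): with strict area overlap a
    short label-clipped bond stub could never reach the symbol's square even
    though the merge likelihood there is well-defined and high.
    """
    if a1.origin == "symbol" and a2.origin == "symbol":
        return a1.overlaps(a2)
    if a1.origin == "bond" and a2.origin == "bond":
        return a1.overlaps(a2)
    bond_c, sym_c = (a1, a2) if a1.origin == "bond" else (a2, a1)
    m = max(bond_c.rb, lmed / 4.0)
    s = sym_c.slb / 2.0 + m
    return _geom.dist(a1.center, a2.center) <= s


def atom_merge_likelihood(a1: AtomCandidate, a2: AtomCandidate, lmed: float) -> float:
    """Distance-decaying probability that two atom candidates are one atom.

    For two bond-ending candidates with radii r1, r2 and center distance d:
    0.9 when d <= Q = max(r1, r2); linear decay 0.7 -> 0.3 on (Q, R] with
    R = min(1.5*Q, r1 + r2); 0.1 beyond R.  For a bond-ending/symbol pair the
    same shape applies with S = sl/2 + max(r, lmed/4) and
    T = min(1.5*S, sl + max(r, lmed/4)); the 0.9 branch additionally requires
    the bond's carrier line to intersect the symbol's bounding square.  Two
    symbol-origin candidates never merge (0.1).
    """
    if a1.origin == "symbol" and a2.origin == "symbol":
        return 0.1
    d = _geom.dist(a1.center, a2.center)
    if a1.origin == "bond" and a2.origin == "bond":
        q = max(a1.rb, a2.rb)
        r = min(1.5 * q, a1.rb + a2.rb)
        if d <= q:
            return 0.9
        if d <= r:
            return 0.7 - 0.4 * (d - q) / (r - q)
        return 0.1
    bond_c, sym_c = (a1, a2) if a1.origin == "bond" else (a2, a1)
    sl = sym_c.slb
    m = max(bond_c.rb, lmed / 4.0)
    s = sl / 2.0 + m
    t = min(1.5 * s, sl + m)
    if d <= s and _carrier_hits_square(bond_c, sym_c):
        return 0.9
    if d <= t:
        # without the carrier-line condition the likelihood saturates at the
        # decay value of the S boundary (0.7); never reaches 0.9
        return min(0.7, 0.7 - 0.4 * (d - s) / (t - s))
    return 0.1


def _carrier_hits_square(bond_c: AtomCandidate, sym_c: AtomCandidate) -> bool:
    """Does the infinite carrier line of the bond cross the symbol's square?

    True iff the square's corners do not all lie on one side of the line."""
    if bond_c.carrier is None:
        return False
    (x1, y1), (x2, y2) = bond_c.carrier
    dx, dy = x2 - x1, y2 - y1
    h = sym_c.slb / 2.0
    cx, cy = sym_c.center
    signs = [
        dx * (cy + sy * h - y1) - dy * (cx + sx * h - x1)
        for sx in (-1, 1)
        for sy in (-1, 1)
    ]
    return min(signs) <= 0.0 <= max(signs)


def rule2b_max_dist(lb: float) -> float:
    """Rule-2b ink-coverage threshold: sampled points must lie within lb/8."""
    return lb / 8.0


# ---------------------------------------------------------------------------
# Markov network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Factor:
    variables: tuple[int, ...]
    table: np.ndarray  # shape (2,) * len(variables)

    def __post_init__(self):
        t = np.asarray(self.table, dtype=float)
        if (t < 0).any() or not (t > 0).any():
            raise ValueError("factor table must be nonnegative with a positive entry")
        object.__setattr__(self, "table", t)


@dataclass
class MarkovNet:
    names: list[str] = field(default_factory=list)  # node index -> name
    kinds: list[str] = field(default_factory=list)  # atom|bond|amerge|bmerge
    factors: list[Factor] = field(default_factory=list)
    index: dict[str, int] = field(default_factory=dict)

    def add_node(self, name: str, kind: str) -> int:
        self.index[name] = len(self.names)
        self.names.append(name)
        self.kinds.append(kind)
        return self.index[name]

    def add_factor(self, variables: tuple[int, ...], table: np.ndarray) -> None:
        self.factors.append(Factor(variables, table))

    def unary_potential(self, name: str) -> np.ndarray | None:
        """The product of single-variable factor tables attached to a node,
        indexed [false, true]."""
        i = self.index[name]
        out = None
        for f in self.factors:
            if f.variables == (i,):
                out = f.table if out is None else out * f.table
        return out

    def to_json(self) -> dict:
        return {
            "nodes": [
                {"name": n, "kind": k} for n, k in zip(self.names, self.kinds)
            ],
            "factors": [
                {"variables": list(f.variables), "table": f.table.ravel().tolist()}
                for f in self.factors
            ],
        }


@dataclass
class Assignment:
    values: dict[str, bool]
    log_score: float

    @property
    def score(self) -> float:
        return math.exp(self.log_score)


def _unary(p_true: float) -> np.ndarray:
    return np.array([1.0 - p_true, p_true])


def build_network(
    atom_cands: list[AtomCandidate],
    bond_cands: list[BondCandidate],
    img: BinaryImage | None,
    lmed: float,
    n_coverage_samples: int = 16,
) -> MarkovNet:
    """Assemble the Markov network from candidates and image evidence.

    Factors follow the four rules: (1) atom existence 0.9 for bond-ending
    candidates, and for symbol candidates whose area overlaps a bond-ending
    candidate's; (2) bond existence 0.9 for non-solid styles, and for solid
    bonds whose sampled segment points all lie within ``length/8`` of ink;
    (3) atom merges gated on both existences with the distance-decaying
    likelihood; (4) bond merges tied to the merges of their ending candidates.
    A rule whose condition fails contributes the reversed table (0.9 on
    false).  Merge nodes only exist for overlapping atom pairs / co-located
    bond pairs.
    """
    net = MarkovNet()
    dist_map = None
    if img is not None:
        dist_map = distance_transform_edt(~img.pixels)

    n_bond_origin = sum(1 for a in atom_cands if a.origin == "bond")
    for i, a in enumerate(atom_cands):
        net.add_node(f"atom:{i}", "atom")
        if a.origin == "bond":
            supported = True
        elif n_bond_origin == 0:
            supported = True  # degenerate molecule: symbols without bonds
        else:
            supported = any(
                other.origin == "bond" and candidates_interact(a, other, lmed)
                for other in atom_cands
                if other is not a
            )
        net.add_factor((net.index[f"atom:{i}"],), _unary(0.9 if supported else 0.1))

    for j, b in enumerate(bond_cands):
        net.add_node(f"bond:{j}", "bond")
        if b.style != BondStyle.SOLID:
            supported = True
        elif dist_map is None:
            supported = True
        else:
            supported = _ink_coverage_ok(b, dist_map, n_coverage_samples)
        net.add_factor((net.index[f"bond:{j}"],), _unary(0.9 if supported else 0.1))

    # atom merge nodes: pairs with overlapping bounding areas
    amerge_index: dict[tuple[int, int], int] = {}
    eps = 0.01
    for i, j in itertools.combinations(range(len(atom_cands)), 2):
        a1, a2 = atom_cands[i], atom_cands[j]
        if not candidates_interact(a1, a2, lmed):
            continue
        node = net.add_node(f"amerge:{i}:{j}", "amerge")
        amerge_index[(i, j)] = node
        p = atom_merge_likelihood(a1, a2, lmed)
        table = np.empty((2, 2, 2))  # [exists1, exists2, merge]
        table[1, 1, 1] = p
        table[1, 1, 0] = 1.0 - p
        for e1, e2 in ((0, 0), (0, 1), (1, 0)):
            table[e1, e2, 1] = eps
            table[e1, e2, 0] = 1.0 - eps
        net.add_factor(
            (net.index[f"atom:{i}"], net.index[f"atom:{j}"], node), table
        )

    # bond merge nodes: pairs with center distance <= longer bond length
    by_bond_end: dict[tuple[int, int], int] = {}
    for idx, a in enumerate(atom_cands):
        if a.origin == "bond":
            by_bond_end[(a.bond_index, a.end_index)] = idx
    for i, j in itertools.combinations(range(len(bond_cands)), 2):
        b1, b2 = bond_cands[i], bond_cands[j]
        if _geom.dist(b1.center, b2.center) > max(b1.length, b2.length):
            continue
        node = net.add_node(f"bmerge:{i}:{j}", "bmerge")
        pairs = _match_ends(b1, b2)
        merge_nodes = []
        for (bi, ei), (bj, ej) in pairs:
            ai = by_bond_end.get((b1.bond_index, ei))
            aj = by_bond_end.get((b2.bond_index, ej))
            if ai is None or aj is None:
                merge_nodes.append(None)
                continue
            key = (min(ai, aj), max(ai, aj))
            merge_nodes.append(amerge_index.get(key))
        present = [m for m in merge_nodes if m is not None]
        if len(present) == 2:
            table = np.empty((2, 2, 2))  # [amerge1, amerge2, bmerge]
            for m1 in (0, 1):
                for m2 in (0, 1):
                    both = m1 == 1 and m2 == 1
                    table[m1, m2, 1] = 0.9 if both else 0.1
                    table[m1, m2, 0] = 0.1 if both else 0.9
            net.add_factor((present[0], present[1], node), table)
        elif len(present) == 1:
            # a missing merge node is a constant False: bmerge should be False
            table = np.empty((2, 2))  # [amerge, bmerge]
            table[:, 1] = 0.1
            table[:, 0] = 0.9
            net.add_factor((present[0], node), table)
        else:
            net.add_factor((node,), _unary(0.1))
    return net


def _match_ends(b1: BondCandidate, b2: BondCandidate):
    """Pair the endings of two bonds by minimal total distance."""
    direct = _geom.dist(b1.end1, b2.end1) + _geom.dist(b1.end2, b2.end2)
    crossed = _geom.dist(b1.end1, b2.end2) + _geom.dist(b1.end2, b2.end1)
    if direct <= crossed:
        return (((0, 0), (0, 0)), ((0, 1), (0, 1)))
    return (((0, 0), (0, 1)), ((0, 1), (0, 0)))


def _ink_coverage_ok(b: BondCandidate, dist_map: np.ndarray, n: int) -> bool:
    thr = rule2b_max_dist(b.length)
    h, w = dist_map.shape
    segs = b.segments if b.segments else ((b.end1, b.end2),)
    for p1, p2 in segs:
        for k in range(n):
            t = (k + 0.5) / n
            x = int(round(p1[0] + t * (p2[0] - p1[0])))
            y = int(round(p1[1] + t * (p2[1] - p1[1])))
            if not (0 <= x < w and 0 <= y < h):
                return False
            if dist_map[y, x] > thr:
                return False
    return True


# ---------------------------------------------------------------------------
# MAP inference
# ---------------------------------------------------------------------------


_KIND_PRIORITY = {"atom": 0, "bond": 0, "amerge": 1, "bmerge": 1}


def map_inference(
    net: MarkovNet,
    enum_limit: int = 20,
    bp_sweeps: int = 50,
    damping: float = 0.5,
    tol: float = 1e-12,
) -> Assignment:
    """MAP state of the network: exact per connected component when small,
    max-product message passing otherwise.

    Ties are broken deterministically: prefer existence variables true, then
    merge variables true, then lower node index.
    """
    n = len(net.names)
    if n == 0:
        return Assignment(values={}, log_score=0.0)
    ds = DisjointSet(range(n))
    for f in net.factors:
        for a, b in zip(f.variables, f.variables[1:]):
            ds.merge(a, b)
    factors_of: dict[int, list[Factor]] = {}
    for f in net.factors:
        root = ds[f.variables[0]]
        factors_of.setdefault(root, []).append(f)
    values = [False] * n
    total_log = 0.0
    for comp in sorted(ds.subsets(), key=lambda c: min(c)):
        comp_vars = sorted(comp)
        comp_factors = factors_of.get(ds[comp_vars[0]], [])
        if len(comp_vars) <= enum_limit:
            assign, lg = _enumerate_map(net, comp_vars, comp_factors, tol)
        else:
            assign, lg = _max_product(net, comp_vars, comp_factors, bp_sweeps, damping, tol)
        for v, val in assign.items():
            values[v] = val
        total_log += lg
    return Assignment(
        values={net.names[i]: bool(values[i]) for i in range(n)},
        log_score=total_log,
    )


def _log_table(table: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(table)


def _tiebreak_key(net: MarkovNet, comp_vars: list[int], bits: np.ndarray) -> tuple:
    order = sorted(
        range(len(comp_vars)),
        key=lambda k: (_KIND_PRIORITY[net.kinds[comp_vars[k]]], comp_vars[k]),
    )
    return tuple(int(bits[k]) for k in order)


def _enumerate_map(net, comp_vars, comp_factors, tol):
    k = len(comp_vars)
    pos = {v: i for i, v in enumerate(comp_vars)}
    logj = np.zeros((2,) * k)
    for f in comp_factors:
        axes = [pos[v] for v in f.variables]
        lt = _log_table(f.table)
        # broadcast the factor table into the joint's (sorted) axis order
        perm = [axes.index(ax) for ax in sorted(axes)]
        shape = [1] * k
        for ax in axes:
            shape[ax] = 2
        logj = logj + np.transpose(lt, perm).reshape(shape)
    flat = logj.ravel()
    best = flat.max()
    if not np.isfinite(best):
        raise ValueError("malformed factor component: all assignments have zero score")
    ties = np.nonzero(flat >= best - tol)[0]
    best_idx = None
    best_key = None
    for t_ in ties:
        bits = np.array(np.unravel_index(int(t_), (2,) * k))
        key = _tiebreak_key(net, comp_vars, bits)
        if best_key is None or key > best_key:
            best_key = key
            best_idx = int(t_)
    bits = np.unravel_index(best_idx, (2,) * k)
    assign = {v: bool(bits[pos[v]]) for v in comp_vars}
    return assign, float(flat[best_idx])


def _max_product(net, comp_vars, comp_factors, sweeps, damping, tol):
    """Loopy max-product in log space with damping and a fixed schedule."""
    var_factors: dict[int, list[int]] = {v: [] for v in comp_vars}
    for fi, f in enumerate(comp_factors):
        for v in f.variables:
            var_factors[v].append(fi)
    msg_vf = {(v, fi): np.zeros(2) for v in comp_vars for fi in var_factors[v]}
    msg_fv = {(fi, v): np.zeros(2) for fi, f in enumerate(comp_factors) for v in f.variables}
    logs = [_log_table(f.table) for f in comp_factors]
    for _ in range(sweeps):
        # variable -> factor
        new_vf = {}
        for (v, fi), old in msg_vf.items():
            m = np.zeros(2)
            for fj in var_factors[v]:
                if fj != fi:
                    m = m + msg_fv[(fj, v)]
            m = m - m.max()
            new_vf[(v, fi)] = damping * old + (1 - damping) * m
        msg_vf = new_vf
        # factor -> variable
        new_fv = {}
        for fi, f in enumerate(comp_factors):
            lt = logs[fi]
            for ai, v in enumerate(f.variables):
                t = lt.copy()
                for aj, u in enumerate(f.variables):
                    if u == v:
                        continue
                    shape = [1] * lt.ndim
                    shape[aj] = 2
                    t = t + msg_vf[(u, fi)].reshape(shape)
                axes = tuple(a for a in range(lt.ndim) if a != ai)
                m = t.max(axis=axes) if axes else t
                m = m - m.max()
                new_fv[(fi, v)] = damping * msg_fv[(fi, v)] + (1 - damping) * m
        msg_fv = new_fv
    assign = {}
    for v in comp_vars:
        belief = np.zeros(2)
        for fi in var_factors[v]:
            belief = belief + msg_fv[(fi, v)]
        if belief[1] >= belief[0] - tol:
            assign[v] = True
        else:
            assign[v] = False
    lg = 0.0
    for fi, f in enumerate(comp_factors):
        idx = tuple(int(assign[v]) for v in f.variables)
        val = logs[fi][idx]
        lg += float(val)
    if not np.isfinite(lg):
        # zero-probability decode (possible on loopy graphs): fall back to a
        # greedy repair of merge variables against their factors
        for fi, f in enumerate(comp_factors):
            idx = tuple(int(assign[v]) for v in f.variables)
            if np.isfinite(logs[fi][idx]):
                continue
            for v in f.variables:
                if net.kinds[v] in ("amerge", "bmerge"):
                    assign[v] = False
        lg = sum(
            float(logs[fi][tuple(int(assign[v]) for v in f.variables)])
            for fi, f in enumerate(comp_factors)
        )
    return assign, lg


# ---------------------------------------------------------------------------
# candidate resolution (growing merge)
# ---------------------------------------------------------------------------


@dataclass
class ResolvedAtom:
    center: Point
    parsed: ParsedAtom
    member_candidates: list[int] = field(default_factory=list)


@dataclass
class ResolvedBond:
    end1: Point
    end2: Point
    degree: int
    style: BondStyle
    atom1: int | None  # indices into the resolved atom list
    atom2: int | None


@dataclass
class ResolvedStructure:
    atoms: list[ResolvedAtom]
    bonds: list[ResolvedBond]


_STYLE_PRIORITY = [
    BondStyle.SOLID_WEDGE,
    BondStyle.DASHED_WEDGE,
    BondStyle.DASHED_LINE,
    BondStyle.WAVY,
    BondStyle.AROMATIC,
    BondStyle.SOLID,
]


def resolve_candidates(
    assignment: Assignment,
    atom_cands: list[AtomCandidate],
    bond_cands: list[BondCandidate],
) -> ResolvedStructure:
    """Grow merged atoms/bonds from the MAP assignment.

    Existence-false candidates are discarded; merge-true pairs are closed
    transitively.  Merged atoms sit at the mean member center and take their
    element from a symbol-origin member (implicit carbon otherwise); merged
    bonds average their endings per side and accumulate degree (capped at 3).
    """
    vals = assignment.values
    a_exists = [vals.get(f"atom:{i}", False) for i in range(len(atom_cands))]
    b_exists = [vals.get(f"bond:{j}", False) for j in range(len(bond_cands))]

    ds = DisjointSet(range(len(atom_cands)))
    for name, v in sorted(vals.items()):
        if not v or not name.startswith("amerge:"):
            continue
        _, i, j = name.split(":")
        i, j = int(i), int(j)
        if a_exists[i] and a_exists[j]:
            ds.merge(i, j)
    atom_groups = [
        sorted(g) for g in ds.subsets() if a_exists[min(g)] or any(a_exists[i] for i in g)
    ]
    atom_groups = [
        [i for i in g if a_exists[i]] for g in atom_groups
    ]
    atom_groups = [g for g in atom_groups if g]
    atom_groups.sort(key=lambda g: g[0])

    atoms: list[ResolvedAtom] = []
    atom_of_cand: dict[int, int] = {}
    for g in atom_groups:
        centers = np.array([atom_cands[i].center for i in g], dtype=float)
        center = (float(centers[:, 0].mean()), float(centers[:, 1].mean()))
        symbol_members = [i for i in g if atom_cands[i].origin == "symbol"]
        parsed = ParsedAtom(kind="atom", element="C")
        if symbol_members:
            parsed_list = [atom_cands[i].group.parsed for i in symbol_members]
            unique_groups = {id(atom_cands[i].group) for i in symbol_members}
            if len({(p.element, p.charge, p.hcount) for p in parsed_list if p}) > 1:
                log.warning("conflicting symbol elements in merged atom; keeping nearest")
                nearest = min(
                    symbol_members,
                    key=lambda i: _geom.dist(atom_cands[i].center, center),
                )
                parsed = atom_cands[nearest].group.parsed
            else:
                parsed = parsed_list[0] or parsed
        idx = len(atoms)
        atoms.append(ResolvedAtom(center=center, parsed=parsed, member_candidates=g))
        for i in g:
            atom_of_cand[i] = idx

    dsb = DisjointSet(range(len(bond_cands)))
    for name, v in sorted(vals.items()):
        if not v or not name.startswith("bmerge:"):
            continue
        _, i, j = name.split(":")
        i, j = int(i), int(j)
        if b_exists[i] and b_exists[j]:
            dsb.merge(i, j)
    bond_groups = [sorted(g) for g in dsb.subsets()]
    bond_groups = [[j for j in g if b_exists[j]] for g in bond_groups]
    bond_groups = [g for g in bond_groups if g]
    bond_groups.sort(key=lambda g: g[0])

    # candidate-end -> atom candidate index
    end_cand: dict[tuple[int, int], int] = {}
    for idx, a in enumerate(atom_cands):
        if a.origin == "bond":
            end_cand[(a.bond_index, a.end_index)] = idx

    bonds: list[ResolvedBond] = []
    for g in bond_groups:
        ref = bond_cands[g[0]]
        u = _geom.unit_direction(ref.end1, ref.end2)
        side1, side2 = [], []
        deg = 0
        style = BondStyle.SOLID
        for j in g:
            b = bond_cands[j]
            deg += b.degree
            for st in _STYLE_PRIORITY:
                if b.style == st and _STYLE_PRIORITY.index(st) < _STYLE_PRIORITY.index(style):
                    style = st
            p1, p2 = b.end1, b.end2
            if _geom.project_onto(p1, ref.end1, u) > _geom.project_onto(p2, ref.end1, u):
                p1, p2 = p2, p1
            side1.append((j, p1))
            side2.append((j, p2))
        if deg > 3:
            log.warning("merged bond degree %d capped at 3", deg)
            deg = 3
        e1 = (
            float(np.mean([p[0] for _, p in side1])),
            float(np.mean([p[1] for _, p in side1])),
        )
        e2 = (
            float(np.mean([p[0] for _, p in side2])),
            float(np.mean([p[1] for _, p in side2])),
        )
        # attach atoms via the representative member's ending candidates
        a1 = a2 = None
        for j, p in side1:
            b = bond_cands[j]
            ei = 0 if p == b.end1 else 1
            ci = end_cand.get((b.bond_index, ei))
            if ci is not None and ci in atom_of_cand:
                a1 = atom_of_cand[ci]
                break
        for j, p in side2:
            b = bond_cands[j]
            ei = 0 if p == b.end1 else 1
            ci = end_cand.get((b.bond_index, ei))
            if ci is not None and ci in atom_of_cand:
                a2 = atom_of_cand[ci]
                break
        bonds.append(
            ResolvedBond(end1=e1, end2=e2, degree=deg, style=style, atom1=a1, atom2=a2)
        )
    return ResolvedStructure(atoms=atoms, bonds=bonds)
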