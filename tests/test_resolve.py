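"""Candidate creation, merge likelihoods, Markov network and MAP inference."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ocsr import resolve
from ocsr.bonds import Bond, BondStyle
from ocsr.raster import BinaryImage


def _bond_cand(center, rb, carrier=None):
    return resolve.AtomCandidate(origin="bond", center=center, rb=rb, carrier=carrier)


def _sym_cand(center, slb):
    return resolve.AtomCandidate(origin="symbol", center=center, slb=slb)


class TestCandidateCreation:
    def test_bond_ending_radius_is_quarter_of_shorter_length(self):
        bond = Bond(style=BondStyle.SOLID, degree=1, end1=(0.0, 0.0), end2=(40.0, 0.0))
        cands = resolve.make_atom_candidates([bond], [], lmed=40.0, slmed=10.0)
        assert len(cands) == 2
        assert all(c.rb == 10.0 for c in cands)

    def test_symbol_square_side_enlarged_to_1_5x(self):
        from ocsr.raster import Shape
        from ocsr.symbols import SymbolGroup

        px = np.array([[x, y] for x in range(20) for y in range(18)])
        group = SymbolGroup(shapes=[Shape(px)], roles=["mainline"])
        cands = resolve.make_atom_candidates([], [group], lmed=40.0, slmed=10.0)
        assert len(cands) == 1
        assert cands[0].slb == pytest.approx(1.5 * 20)

    def test_bond_candidates_copy_endings_and_degree(self):
        bonds = [
            Bond(style=BondStyle.SOLID, degree=2, end1=(0.0, 0.0), end2=(40.0, 0.0)),
            Bond(style=BondStyle.WAVY, degree=1, end1=(0.0, 10.0), end2=(40.0, 10.0)),
        ]
        cands = resolve.make_bond_candidates(bonds)
        assert [c.degree for c in cands] == [2, 1]
        assert cands[0].end1 == (0.0, 0.0)

    def test_no_bonds_no_candidates(self):
        assert resolve.make_bond_candidates([]) == []


class TestMergeLikelihood:
    def test_close_bond_ending_pair_is_090(self):
        a1 = _bond_cand((0.0, 0.0), 5.0)
        a2 = _bond_cand((3.0, 0.0), 5.0)
        assert resolve.atom_merge_likelihood(a1, a2, lmed=40.0) == pytest.approx(0.9)

    def test_distant_bond_ending_pair_is_010(self):
        a1 = _bond_cand((0.0, 0.0), 5.0)
        a2 = _bond_cand((9.0, 0.0), 5.0)
        assert resolve.atom_merge_likelihood(a1, a2, lmed=40.0) == pytest.approx(0.1)

    def test_midband_decay_value(self):
        # r1 = r2 = 5 => Q = 5, R = 7.5; at d = 6.25 the decay gives 0.5
        a1 = _bond_cand((0.0, 0.0), 5.0)
        a2 = _bond_cand((6.25, 0.0), 5.0)
        assert resolve.atom_merge_likelihood(a1, a2, lmed=40.0) == pytest.approx(0.5)

    def test_two_symbol_candidates_never_merge(self):
        assert resolve.atom_merge_likelihood(
            _sym_cand((0.0, 0.0), 20.0), _sym_cand((1.0, 0.0), 20.0), lmed=40.0
        ) == pytest.approx(0.1)

    def test_mixed_pair_carrier_line_required_for_090(self):
        sym = _sym_cand((30.0, 0.0), 20.0)
        pointing = _bond_cand((15.0, 0.0), 10.0, carrier=((0.0, 0.0), (15.0, 0.0)))
        missing = _bond_cand((15.0, 0.0), 10.0, carrier=((0.0, 40.0), (15.0, 40.0)))
        assert resolve.atom_merge_likelihood(pointing, sym, lmed=40.0) == pytest.approx(0.9)
        assert resolve.atom_merge_likelihood(missing, sym, lmed=40.0) <= 0.7

    @given(st.floats(0.0, 30.0), st.floats(0.0, 30.0))
    @settings(max_examples=60, deadline=None)
    def test_monotone_nonincreasing_in_distance(self, d1, d2):
        lo, hi = sorted((d1, d2))
        a = _bond_cand((0.0, 0.0), 5.0)
        p_lo = resolve.atom_merge_likelihood(a, _bond_cand((lo, 0.0), 6.0), lmed=40.0)
        p_hi = resolve.atom_merge_likelihood(a, _bond_cand((hi, 0.0), 6.0), lmed=40.0)
        assert p_lo >= p_hi - 1e-12

    def test_left_limit_of_decay_branch_is_07(self):
        a1 = _bond_cand((0.0, 0.0), 5.0)
        p = resolve.atom_merge_likelihood(a1, _bond_cand((5.0 + 1e-9, 0.0), 5.0), lmed=40.0)
        assert p == pytest.approx(0.7, abs=1e-6)


def _line_image(p1, p2, shape=(60, 120)):
    arr = np.zeros(shape, dtype=bool)
    n = int(math.dist(p1, p2)) + 1
    for t in np.linspace(0, 1, 2 * n):
        x = int(round(p1[0] + t * (p2[0] - p1[0])))
        y = int(round(p1[1] + t * (p2[1] - p1[1])))
        arr[y, x] = True
    return BinaryImage(arr)


class TestBuildNetwork:
    def test_overlapping_endings_get_a_merge_node(self):
        b1 = Bond(style=BondStyle.SOLID, degree=1, end1=(0.0, 10.0), end2=(40.0, 10.0))
        b2 = Bond(style=BondStyle.SOLID, degree=1, end1=(43.0, 10.0), end2=(80.0, 10.0))
        cands = resolve.make_atom_candidates([b1, b2], [], lmed=40.0, slmed=10.0)
        net = resolve.build_network(cands, resolve.make_bond_candidates([b1, b2]), None, 40.0)
        assert sum(k == "amerge" for k in net.kinds) >= 1
        assert sum(k == "atom" for k in net.kinds) == 4

    def test_far_bonds_get_no_bond_merge_node(self):
        b1 = Bond(style=BondStyle.SOLID, degree=1, end1=(0.0, 0.0), end2=(20.0, 0.0))
        b2 = Bond(style=BondStyle.SOLID, degree=1, end1=(100.0, 0.0), end2=(120.0, 0.0))
        cands = resolve.make_atom_candidates([b1, b2], [], lmed=40.0, slmed=10.0)
        net = resolve.build_network(cands, resolve.make_bond_candidates([b1, b2]), None, 40.0)
        assert sum(k == "bmerge" for k in net.kinds) == 0

    def test_ink_covered_solid_bond_gets_09_existence(self):
        img = _line_image((10, 30), (90, 30))
        b = Bond(style=BondStyle.SOLID, degree=1, end1=(10.0, 30.0), end2=(90.0, 30.0))
        cands = resolve.make_atom_candidates([b], [], lmed=80.0, slmed=10.0)
        net = resolve.build_network(cands, resolve.make_bond_candidates([b]), img, 80.0)
        table = net.unary_potential("bond:0")
        assert table[1] == pytest.approx(0.9)

    def test_uncovered_solid_bond_gets_reversed_table(self):
        img = BinaryImage(np.zeros((60, 120), dtype=bool))
        b = Bond(style=BondStyle.SOLID, degree=1, end1=(10.0, 30.0), end2=(90.0, 30.0))
        cands = resolve.make_atom_candidates([b], [], lmed=80.0, slmed=10.0)
        net = resolve.build_network(cands, resolve.make_bond_candidates([b]), img, 80.0)
        assert net.unary_potential("bond:0")[1] == pytest.approx(0.1)

    def test_rule2b_threshold_is_length_over_eight(self):
        assert resolve.rule2b_max_dist(80.0) == pytest.approx(10.0)


def _random_net(n, rng):
    net = resolve.MarkovNet()
    kinds = ["atom", "bond", "amerge", "bmerge"]
    for i in range(n):
        net.add_node(f"{kinds[i % 4]}:{i}", kinds[i % 4])
        net.add_factor((i,), rng.uniform(0.05, 0.95, size=2))
    for _ in range(int(rng.integers(1, max(2, n)))):
        k = min(int(rng.integers(2, 4)), n)
        vars_ = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
        net.add_factor(vars_, rng.uniform(0.05, 0.95, size=(2,) * k))
    return net


def _brute_force_map(net, n):
    best = -math.inf
    for bits in itertools.product([0, 1], repeat=n):
        score = sum(
            math.log(f.table[tuple(bits[i] for i in f.variables)]) for f in net.factors
        )
        best = max(best, score)
    return best


class TestMapInference:
    def test_single_node_argmax(self):
        net = resolve.MarkovNet()
        net.add_node("atom:0", "atom")
        net.add_factor((0,), np.array([0.1, 0.9]))
        out = resolve.map_inference(net)
        assert out.values["atom:0"] is True
        assert out.score == pytest.approx(0.9)

    def test_empty_network(self):
        out = resolve.map_inference(resolve.MarkovNet())
        assert out.values == {} and out.score == 1.0

    def test_enumeration_matches_brute_force_on_random_components(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            net = _random_net(n, rng)
            got = resolve.map_inference(net)
            assert got.log_score == pytest.approx(_brute_force_map(net, n), abs=1e-9)

    def test_max_product_exact_on_tree_networks(self):
        # chains are trees: max-product is exact there
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(3, 10))
            net = resolve.MarkovNet()
            for i in range(n):
                net.add_node(f"atom:{i}", "atom")
                net.add_factor((i,), rng.uniform(0.05, 0.95, size=2))
            for i in range(n - 1):
                net.add_factor((i, i + 1), rng.uniform(0.05, 0.95, size=(2, 2)))
            got = resolve.map_inference(net, enum_limit=1)  # force message passing
            assert got.log_score == pytest.approx(_brute_force_map(net, n), abs=1e-6)

    def test_malformed_all_zero_factor_rejected(self):
        net = resolve.MarkovNet()
        net.add_node("atom:0", "atom")
        with pytest.raises(ValueError):
            net.add_factor((0,), np.zeros(2))


class TestResolveCandidates:
    def _assignment(self, cands, bond_cands, lmed=40.0):
        net = resolve.build_network(cands, bond_cands, None, lmed)
        return resolve.map_inference(net)

    def test_chained_merges_collapse_to_one_atom(self):
        bonds = [
            Bond(style=BondStyle.SOLID, degree=1, end1=(0.0, 0.0), end2=(40.0, 0.0)),
            Bond(style=BondStyle.SOLID, degree=1, end1=(42.0, 0.0), end2=(82.0, 0.0)),
            Bond(style=BondStyle.SOLID, degree=1, end1=(44.0, 2.0), end2=(44.0, 42.0)),
        ]
        cands = resolve.make_atom_candidates(bonds, [], lmed=40.0, slmed=10.0)
        bcands = resolve.make_bond_candidates(bonds)
        out = resolve.resolve_candidates(self._assignment(cands, bcands), cands, bcands)
        # three bond endings near (42, 0) grow into a single junction atom
        assert len(out.atoms) == 4
        junction = min(out.atoms, key=lambda a: math.dist(a.center, (43, 1)))
        assert math.dist(junction.center, (43.3, 0.7)) < 3.0
        incident = sum(
            1 for b in out.bonds if junction in (out.atoms[b.atom1], out.atoms[b.atom2])
        )
        assert incident == 3

    def test_parallel_duplicate_bonds_accumulate_degree(self):
        bonds = [
            Bond(style=BondStyle.SOLID, degree=1, end1=(0.0, 0.0), end2=(40.0, 0.0)),
            Bond(style=BondStyle.SOLID, degree=1, end1=(0.0, 3.0), end2=(40.0, 3.0)),
        ]
        cands = resolve.make_atom_candidates(bonds, [], lmed=40.0, slmed=10.0)
        bcands = resolve.make_bond_candidates(bonds)
        out = resolve.resolve_candidates(self._assignment(cands, bcands), cands, bcands)
        assert len(out.bonds) == 1
        assert out.bonds[0].degree == 2

    def test_resolution_invariant_to_candidate_order(self):
        bonds = [
            Bond(style=BondStyle.SOLID, degree=1, end1=(0.0, 0.0), end2=(40.0, 0.0)),
            Bond(style=BondStyle.SOLID, degree=1, end1=(42.0, 0.0), end2=(82.0, 0.0)),
        ]
        outs = []
        for order in (bonds, bonds[::-1]):
            cands = resolve.make_atom_candidates(order, [], lmed=40.0, slmed=10.0)
            bcands = resolve.make_bond_candidates(order)
            out = resolve.resolve_candidates(self._assignment(cands, bcands), cands, bcands)
            outs.append(sorted(tuple(np.round(a.center, 6)) for a in out.atoms))
        assert outs[0] == outs[1]

    def test_furcation_with_jitter_resolves_to_single_atom(self):
        # three bond endings jittered by <= rb/2 around one junction
        rng = np.random.default_rng(0)
        center = np.array([60.0, 60.0])
        bonds = []
        for ang in (0, 120, 240):
            u = np.array([math.cos(math.radians(ang)), math.sin(math.radians(ang))])
            jit = rng.uniform(-2.5, 2.5, size=2)  # rb = 10 here
            start = center + jit
            bonds.append(
                Bond(style=BondStyle.SOLID, degree=1,
                     end1=tuple(start), end2=tuple(start + 40 * u))
            )
        cands = resolve.make_atom_candidates(bonds, [], lmed=40.0, slmed=10.0)
        bcands = resolve.make_bond_candidates(bonds)
        out = resolve.resolve_candidates(self._assignment(cands, bcands), cands, bcands)
        assert len(out.atoms) == 4
        hub = min(out.atoms, key=lambda a: math.dist(a.center, tuple(center)))
        incident = sum(1 for b in out.bonds if hub in (out.atoms[b.atom1], out.atoms[b.atom2]))
        assert incident == 3

    def test_symbol_member_sets_the_element(self):
        from ocsr.raster import Shape
        from ocsr.symbols import ParsedAtom, SymbolGroup

        px = np.array([[x, y] for x in range(36, 50) for y in range(-7, 7)])
        group = SymbolGroup(shapes=[Shape(px)], roles=["mainline"])
        group.parsed = ParsedAtom(kind="atom", element="N")
        bond = Bond(style=BondStyle.SOLID, degree=1, end1=(0.0, 0.0), end2=(36.0, 0.0))
        cands = resolve.make_atom_candidates([bond], [group], lmed=40.0, slmed=14.0)
        bcands = resolve.make_bond_candidates([bond])
        out = resolve.resolve_candidates(self._assignment(cands, bcands), cands, bcands)
        elements = {a.parsed.element for a in out.atoms}
        assert "N" in elements and "C" in elements
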