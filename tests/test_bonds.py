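"""Bond typing: multibond grouping, splitting, wedge/dashed/wavy/aromatic."""

import math

import numpy as np
from PIL import Image, ImageDraw

from ocsr import bonds as bonds_mod
from ocsr import fixtures, fmlines, raster
from ocsr.bonds import Bond, BondStyle


def _line(p1, p2):
    n = max(2, int(math.dist(p1, p2)))
    ts = np.linspace(0, 1, n)
    px = np.unique(
        np.column_stack(
            [np.rint(p1[0] + ts * (p2[0] - p1[0])), np.rint(p1[1] + ts * (p2[1] - p1[1]))]
        ).astype(int),
        axis=0,
    )
    return fmlines.DetectedLine(end1=p1, end2=p2, pixels=px)


class TestGroupMultibonds:
    def test_two_close_parallels_become_double_bond(self):
        lines = [_line((10.0, 10.0), (50.0, 10.0)), _line((10.0, 16.0), (50.0, 16.0))]
        (bond,) = bonds_mod.group_multibonds(lines, lmed=40.0)
        assert bond.degree == 2
        assert bond.end1 == (10.0, 13.0) and bond.end2 == (50.0, 13.0)

    def test_single_line_stays_single_bond(self):
        (bond,) = bonds_mod.group_multibonds([_line((0.0, 0.0), (40.0, 0.0))], lmed=40.0)
        assert bond.degree == 1
        assert (bond.end1, bond.end2) == ((0.0, 0.0), (40.0, 0.0))

    def test_distant_parallels_stay_separate(self):
        lines = [_line((10.0, 10.0), (50.0, 10.0)), _line((10.0, 50.0), (50.0, 50.0))]
        out = bonds_mod.group_multibonds(lines, lmed=40.0)
        assert [b.degree for b in out] == [1, 1]

    def test_three_parallels_become_triple(self):
        lines = [
            _line((10.0, 10.0), (50.0, 10.0)),
            _line((10.0, 16.0), (50.0, 16.0)),
            _line((10.0, 22.0), (50.0, 22.0)),
        ]
        (bond,) = bonds_mod.group_multibonds(lines, lmed=40.0)
        assert bond.degree == 3


class TestSplitAtIntersections:
    def test_interior_crossing_splits_into_four(self):
        a = Bond(style=BondStyle.SOLID, degree=1, end1=(0.0, 30.0), end2=(60.0, 30.0))
        b = Bond(style=BondStyle.SOLID, degree=1, end1=(30.0, 0.0), end2=(30.0, 60.0))
        out = bonds_mod.split_at_intersections([a, b], lmed=60.0)
        assert len(out) == 4
        for bond in out:
            assert min(math.dist(bond.end1, (30, 30)), math.dist(bond.end2, (30, 30))) < 1e-6

    def test_shared_endpoint_v_shape_unchanged(self):
        a = Bond(style=BondStyle.SOLID, degree=1, end1=(0.0, 0.0), end2=(30.0, 30.0))
        b = Bond(style=BondStyle.SOLID, degree=1, end1=(30.0, 30.0), end2=(60.0, 0.0))
        assert len(bonds_mod.split_at_intersections([a, b], lmed=40.0)) == 2

    def test_parallel_segments_unchanged(self):
        a = Bond(style=BondStyle.SOLID, degree=1, end1=(0.0, 0.0), end2=(40.0, 0.0))
        b = Bond(style=BondStyle.SOLID, degree=1, end1=(0.0, 10.0), end2=(40.0, 10.0))
        assert len(bonds_mod.split_at_intersections([a, b], lmed=40.0)) == 2


class TestSplitCollinear:
    def test_long_line_split_where_parallel_short_line_ends(self):
        long = Bond(style=BondStyle.SOLID, degree=1, end1=(0.0, 10.0), end2=(80.0, 10.0))
        short = Bond(style=BondStyle.SOLID, degree=1, end1=(40.0, 16.0), end2=(80.0, 16.0))
        out = bonds_mod.split_collinear([long, short], lmed=40.0)
        degrees = sorted(b.degree for b in out)
        assert degrees == [1, 2]
        single = next(b for b in out if b.degree == 1)
        double = next(b for b in out if b.degree == 2)
        assert abs(single.length - 40) <= 2
        assert abs(double.length - 40) <= 2
        assert double.center[0] > single.center[0]

    def test_no_parallel_neighbour_unchanged(self):
        long = Bond(style=BondStyle.SOLID, degree=1, end1=(0.0, 10.0), end2=(80.0, 10.0))
        out = bonds_mod.split_collinear([long], lmed=40.0)
        assert len(out) == 1 and out[0].degree == 1

    def test_full_overlap_left_to_multibond_grouping(self):
        a = Bond(style=BondStyle.SOLID, degree=1, end1=(0.0, 10.0), end2=(40.0, 10.0))
        b = Bond(style=BondStyle.SOLID, degree=1, end1=(0.0, 16.0), end2=(40.0, 16.0))
        out = bonds_mod.split_collinear([a, b], lmed=40.0)
        assert sorted(x.degree for x in out) == [1, 1]


def _render_single(style, length=40.0, stroke=2):
    spec = fixtures.MoleculeSpec(
        atoms=[fixtures.AtomSpec(pos=(0.0, 0.0)), fixtures.AtomSpec(pos=(length / 40.0, 0.0))],
        bonds=[fixtures.BondSpec(0, 1, style=style)],
    )
    return fixtures.render(spec, stroke=stroke)


class TestDetectSolidWedges:
    def test_rendered_wedge_is_marked(self):
        fx = _render_single("wedge")
        skel = raster.thin(fx.image)
        lines = fmlines.fragment_merging(skel)
        bonds = bonds_mod.group_multibonds(lines, lmed=40.0)
        out = bonds_mod.detect_solid_wedges(bonds, fx.image)
        assert any(b.style == BondStyle.SOLID_WEDGE for b in out)

    def test_uniform_stroke_is_not_a_wedge(self):
        fx = _render_single("solid")
        skel = raster.thin(fx.image)
        lines = fmlines.fragment_merging(skel)
        bonds = bonds_mod.group_multibonds(lines, lmed=40.0)
        out = bonds_mod.detect_solid_wedges(bonds, fx.image)
        assert all(b.style == BondStyle.SOLID for b in out)

    def test_multibond_skipped(self):
        b = Bond(style=BondStyle.SOLID, degree=2, end1=(0.0, 10.0), end2=(40.0, 10.0))
        img = raster.BinaryImage(np.zeros((20, 60), dtype=bool))
        out = bonds_mod.detect_solid_wedges([b], img)
        assert out[0].degree == 2 and out[0].style == BondStyle.SOLID


class TestDetectDashed:
    def _dash_shapes(self, lengths, spacing=10, angle_deg=90):
        im = Image.new("L", (120, 80), 255)
        d = ImageDraw.Draw(im)
        a = math.radians(angle_deg)
        u = (math.cos(a), math.sin(a))
        for k, half in enumerate([l / 2 for l in lengths]):
            cx, cy = 20 + k * spacing, 40
            d.line(
                [(cx + u[0] * half, cy + u[1] * half), (cx - u[0] * half, cy - u[1] * half)],
                fill=0,
                width=1,
            )
        img = raster.BinaryImage(np.array(im) < 128)
        return raster.extract_shapes(img)

    def test_equal_dashes_become_dashed_line(self):
        shapes = self._dash_shapes([8] * 5)
        bonds, rest = bonds_mod.detect_dashed([], list(shapes), list(shapes), lmed=40.0)
        assert [b.style for b in bonds] == [BondStyle.DASHED_LINE]
        assert abs(bonds[0].length - 50) <= 6  # spans the group plus half spacing

    def test_growing_dashes_become_dashed_wedge(self):
        shapes = self._dash_shapes([4, 6, 8, 10, 12])
        bonds, rest = bonds_mod.detect_dashed([], list(shapes), list(shapes), lmed=40.0)
        assert [b.style for b in bonds] == [BondStyle.DASHED_WEDGE]

    def test_three_dashes_do_not_make_a_bond(self):
        shapes = self._dash_shapes([8] * 3)
        bonds, rest = bonds_mod.detect_dashed([], list(shapes), list(shapes), lmed=40.0)
        assert bonds == []
        assert len(rest) == 3


class TestDetectWavy:
    def test_rendered_squiggle_becomes_wavy_bond(self):
        fx = _render_single("wavy", length=40.0)
        big = np.kron(fx.image.pixels, np.ones((2, 2), dtype=bool))
        skel = raster.thin(raster.BinaryImage(big))
        shapes = raster.extract_shapes(skel)
        bonds, rest = bonds_mod.detect_wavy([], shapes, lmed=80.0)
        assert [b.style for b in bonds] == [BondStyle.WAVY]
        length = math.dist(bonds[0].end1, bonds[0].end2)
        assert abs(length - 80) <= 8

    def test_letter_o_is_not_wavy(self):
        from ocsr import font

        glyph = np.kron(font.glyph_bitmap("O", 3), np.ones((1, 1), dtype=bool))
        canvas = np.zeros((60, 60), dtype=bool)
        canvas[10 : 10 + glyph.shape[0], 10 : 10 + glyph.shape[1]] = glyph
        shapes = raster.extract_shapes(raster.BinaryImage(canvas))
        bonds, rest = bonds_mod.detect_wavy([], shapes, lmed=40.0)
        assert bonds == []

    def test_straight_dash_rejected(self):
        arr = np.zeros((30, 60), dtype=bool)
        arr[15, 10:50] = True
        shapes = raster.extract_shapes(raster.BinaryImage(arr))
        bonds, rest = bonds_mod.detect_wavy([], shapes, lmed=40.0)
        assert bonds == []


class TestMarkAromaticRings:
    def _hexagon_bonds(self, side=40.0):
        import math as m

        pts = [
            (100 + side * m.cos(m.radians(60 * k + 30)), 100 + side * m.sin(m.radians(60 * k + 30)))
            for k in range(6)
        ]
        return [
            Bond(style=BondStyle.SOLID, degree=1, end1=pts[k], end2=pts[(k + 1) % 6])
            for k in range(6)
        ]

    def test_circle_inside_hexagon_flags_all_six_edges(self):
        bonds = self._hexagon_bonds()
        circle = raster.Circle(center=(100.0, 100.0), radius=20.0, arc=2 * math.pi)
        out = bonds_mod.mark_aromatic_rings(bonds, [circle], lmed=40.0)
        assert sum(b.style == BondStyle.AROMATIC for b in out) == 6

    def test_hexagon_without_circle_keeps_plain_bonds(self):
        out = bonds_mod.mark_aromatic_rings(self._hexagon_bonds(), [], lmed=40.0)
        assert all(b.style == BondStyle.SOLID for b in out)

    def test_circle_in_empty_space_flags_nothing(self):
        bonds = self._hexagon_bonds()
        lonely = raster.Circle(center=(400.0, 400.0), radius=20.0, arc=2 * math.pi)
        out = bonds_mod.mark_aromatic_rings(bonds, [lonely], lmed=40.0)
        assert all(b.style == BondStyle.SOLID for b in out)


class TestDegreeConservation:
    def test_splitting_preserves_line_multiplicity(self):
        a = Bond(style=BondStyle.SOLID, degree=1, end1=(0.0, 30.0), end2=(60.0, 30.0))
        b = Bond(style=BondStyle.SOLID, degree=1, end1=(30.0, 0.0), end2=(30.0, 60.0))
        before = sum(x.degree * x.length for x in (a, b))
        out = bonds_mod.split_at_intersections([a, b], lmed=60.0)
        after = sum(x.degree * x.length for x in out)
        assert math.isclose(before, after, rel_tol=1e-6)

    def test_each_bond_has_exactly_one_style(self):
        fx = _render_single("wedge")
        skel = raster.thin(fx.image)
        lines = fmlines.fragment_merging(skel)
        bonds = bonds_mod.group_multibonds(lines, lmed=40.0)
        bonds = bonds_mod.detect_solid_wedges(bonds, fx.image)
        for b in bonds:
            assert isinstance(b.style, BondStyle)
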