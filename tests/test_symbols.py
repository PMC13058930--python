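"""Symbol grouping, role classification, stub OCR, parsing and corrections."""

import numpy as np
import pytest

from ocsr import assemble, fixtures, font, raster, symbols
from ocsr.symbols import StubOcr


def _glyph_canvas(chars, scale=2, gap=2, sub=(), sup=()):
    """Compose glyphs left to right; chars in `sub`/`sup` are small and
    lowered/raised like the fixture renderer's layout."""
    h = font.GLYPH_H * scale
    canvas = np.zeros((2 * h, 20 + len(chars) * (font.GLYPH_W * scale + gap)), dtype=bool)
    x = 5
    for i, ch in enumerate(chars):
        s = max(1, scale - 1) if (i in sub or i in sup) else scale
        bm = font.glyph_bitmap(ch, s)
        if i in sub:
            y = h // 2 + h - bm.shape[0] // 2 - bm.shape[0] // 2
            y = h // 2 + h - bm.shape[0]
        elif i in sup:
            y = h // 2 - bm.shape[0] // 2
        else:
            y = h // 2
        canvas[y : y + bm.shape[0], x : x + bm.shape[1]] |= bm
        x += bm.shape[1] + gap
    return raster.BinaryImage(canvas)


class TestStubOcr:
    def test_full_alphabet_recognized_exactly(self, stub_ocr):
        for ch in font.ALPHABET:
            for scale in (1, 2, 3):
                bm = font.glyph_bitmap(ch, scale)
                text, conf = stub_ocr.recognize(bm)
                assert text == ch, (ch, scale, text)
                assert conf == 1.0

    def test_multi_glyph_block_reads_left_to_right(self, stub_ocr):
        img = _glyph_canvas("OH")
        text, conf = stub_ocr.recognize(img.pixels)
        assert text == "OH"

    def test_empty_block_gives_empty_text(self, stub_ocr):
        assert stub_ocr.recognize(np.zeros((5, 5), dtype=bool))[0] == ""

    def test_unknown_blob_maps_to_star(self, stub_ocr):
        rng = np.random.default_rng(0)
        blob = rng.random((14, 10)) < 0.5
        text, conf = stub_ocr.recognize(blob)
        assert "*" in text or conf < 0.75


class TestGroupingAndRoles:
    def test_adjacent_glyphs_form_one_group(self):
        img = _glyph_canvas("NH2", sub=(2,))
        shapes = raster.extract_shapes(img)
        groups = symbols.group_nearby(shapes)
        assert len(groups) == 1
        assert len(groups[0].shapes) == 3

    def test_distant_glyphs_form_two_groups(self):
        canvas = np.zeros((30, 200), dtype=bool)
        bm = font.glyph_bitmap("O", 2)
        canvas[5 : 5 + bm.shape[0], 5 : 5 + bm.shape[1]] = bm
        canvas[5 : 5 + bm.shape[0], 150 : 150 + bm.shape[1]] = bm
        groups = symbols.group_nearby(raster.extract_shapes(raster.BinaryImage(canvas)))
        assert len(groups) == 2

    def test_empty_input_no_groups(self):
        assert symbols.group_nearby([]) == []

    def test_lowered_small_digit_is_subscript(self):
        img = _glyph_canvas("NH2", sub=(2,))
        (group,) = symbols.group_nearby(raster.extract_shapes(img))
        symbols.classify_roles(group)
        assert sorted(group.roles) == ["mainline", "mainline", "subscript"]

    def test_raised_small_minus_is_superscript(self):
        img = _glyph_canvas("O-", sup=(1,))
        (group,) = symbols.group_nearby(raster.extract_shapes(img))
        symbols.classify_roles(group)
        assert group.roles == ["mainline", "superscript"]

    def test_single_glyph_is_mainline(self):
        img = _glyph_canvas("N")
        (group,) = symbols.group_nearby(raster.extract_shapes(img))
        symbols.classify_roles(group)
        assert group.roles == ["mainline"]


class TestOcrBlocksAndParse:
    def _parsed(self, chars, stub, **kwargs):
        img = _glyph_canvas(chars, **kwargs)
        (group,) = symbols.group_nearby(raster.extract_shapes(img))
        symbols.classify_roles(group)
        symbols.ocr_blocks(group, stub, img)
        return symbols.parse_group(group, symbols.load_abbreviations())

    def test_nh2_parses_to_nitrogen_with_two_hydrogens(self, stub_ocr):
        g = self._parsed("NH2", stub_ocr, sub=(2,))
        assert (g.parsed.element, g.parsed.hcount, g.parsed.charge) == ("N", 2, 0)

    def test_o_minus_parses_to_charged_oxygen(self, stub_ocr):
        g = self._parsed("O-", stub_ocr, sup=(1,))
        assert (g.parsed.element, g.parsed.charge) == ("O", -1)

    def test_two_minus_superscript_gives_double_charge(self, stub_ocr):
        g = self._parsed("O2-", stub_ocr, sup=(1, 2))
        assert g.parsed.charge == -2

    def test_abbreviation_falls_back_to_dictionary(self, stub_ocr):
        g = self._parsed("Me", stub_ocr)
        assert g.parsed.kind == "abbrev" and g.parsed.abbrev == "Me"

    def test_unresolvable_text_becomes_unknown_atom(self, stub_ocr):
        g = self._parsed("zz", stub_ocr)
        assert g.parsed.kind == "unknown" and g.parsed.element == "*"

    def test_malformed_charge_flagged_and_zeroed(self):
        charge, flags = symbols._parse_charge("++-")
        assert charge == 0 and flags

    def test_cl_two_letter_element(self, stub_ocr):
        g = self._parsed("Cl", stub_ocr)
        assert g.parsed.element == "Cl" and g.parsed.kind == "atom"


class TestCorrections:
    def _pipeline_debug(self, spec):
        fx = fixtures.render(spec)
        debug = assemble.PipelineDebug()
        assemble.recognize_graph(fx.image, debug=debug)
        return fx, debug

    def test_letter_strokes_reclaimed_from_bonds(self):
        # an N label: its vertical strokes are line-detector bait
        spec = fixtures.MoleculeSpec(
            atoms=[
                fixtures.AtomSpec(pos=(0.0, 0.0)),
                fixtures.AtomSpec(element="N", pos=(1.0, 0.0)),
            ],
            bonds=[fixtures.BondSpec(0, 1)],
        )
        fx, debug = self._pipeline_debug(spec)
        texts = [g.texts.get("mainline") for g in debug.groups]
        assert "N" in texts

    def test_oblique_thin_symbol_restored_as_bond(self):
        arr = np.zeros((60, 60), dtype=bool)
        for k in range(40):  # 40-px thin stroke at 45 degrees
            arr[10 + k, 10 + k] = True
        img = raster.BinaryImage(arr)
        shapes = raster.extract_shapes(img)
        kept, bonds = symbols.correct_symbol_false_positives(shapes, [], img, lmed=40.0)
        assert kept == [] and len(bonds) == 1

    def test_axis_aligned_thin_symbol_stays_symbol(self):
        arr = np.zeros((60, 20), dtype=bool)
        arr[10:40, 10] = True  # a letter-l-like vertical stroke
        img = raster.BinaryImage(arr)
        shapes = raster.extract_shapes(img)
        kept, bonds = symbols.correct_symbol_false_positives(shapes, [], img, lmed=40.0)
        assert len(kept) == 1 and bonds == []

    def test_corrections_are_a_fixed_point(self, stub_ocr):
        spec = fixtures.random_spec(8, seed=21, hetero=True)
        fx = fixtures.render(spec)
        binary = raster.binarize(np.where(fx.image.pixels, 0, 255).astype(np.uint8))
        work, scale = raster.trim_pad_upscale(binary)
        skel = raster.thin(work)
        from ocsr import fmlines
        from ocsr import bonds as bonds_mod

        lines = fmlines.fragment_merging(skel)
        lmed = bonds_mod.median_line_length(lines)
        bonds = bonds_mod.group_multibonds(lines, lmed)
        comps = raster.extract_shapes(work)
        b1, s1 = symbols.correct_bond_false_positives(bonds, comps, skel, stub_ocr, lmed)
        s1b, b1b = symbols.correct_symbol_false_positives(s1, b1, skel, lmed)
        # second pass changes nothing
        b2, s2 = symbols.correct_bond_false_positives(b1b, comps, skel, stub_ocr, lmed)
        s2b, b2b = symbols.correct_symbol_false_positives(s2, b2, skel, lmed)
        assert len(b2b) == len(b1b)
        assert {tuple(map(tuple, s.pixels)) for s in s2b} == {
            tuple(map(tuple, s.pixels)) for s in s1b
        }


class TestCollectSymbolShapes:
    def _stage(self, spec):
        from ocsr import bonds as bonds_mod
        from ocsr import fmlines

        fx = fixtures.render(spec)
        binary = raster.binarize(np.where(fx.image.pixels, 0, 255).astype(np.uint8))
        work, _ = raster.trim_pad_upscale(binary)
        skel = raster.thin(work)
        lines = fmlines.fragment_merging(skel)
        lmed = bonds_mod.median_line_length(lines)
        bonds = bonds_mod.group_multibonds(lines, lmed)
        comps = raster.extract_shapes(work)
        stroke = work.ink_count / max(skel.ink_count, 1)
        return symbols.collect_symbol_shapes(
            comps, bonds, skel, lmed, claim_radius=max(2.5, stroke / 2 + 1.5)
        )

    def test_pure_hydrocarbon_leaves_no_symbols(self):
        from conftest import hexagon_spec

        shapes = self._stage(hexagon_spec())
        assert all(s.area < 40 for s in shapes)  # at most junction slivers

    def test_remaining_glyph_is_collected(self):
        # a bond stroke plus an F glyph; the bond's own pixels are claimed
        from ocsr.bonds import Bond, BondStyle

        arr = np.zeros((40, 120), dtype=bool)
        arr[20, 5:60] = True
        glyph = font.glyph_bitmap("F", 2)
        arr[13 : 13 + glyph.shape[0], 70 : 70 + glyph.shape[1]] = glyph
        img = raster.BinaryImage(arr)
        coords = np.array([[x, 20] for x in range(5, 60)])
        bond = Bond(style=BondStyle.SOLID, degree=1, end1=(5.0, 20.0),
                    end2=(59.0, 20.0), coords=coords)
        comps = raster.extract_shapes(img)
        out = symbols.collect_symbol_shapes(comps, [bond], img, lmed=54.0)
        assert len(out) == 1
        assert out[0].bbox[0] >= 70  # it is the glyph, not the stroke

    def test_small_speck_filtered(self):
        arr = np.zeros((30, 30), dtype=bool)
        arr[10, 10] = arr[10, 11] = True  # 2-px speck
        img = raster.BinaryImage(arr)
        comps = raster.extract_shapes(img)
        out = symbols.collect_symbol_shapes(comps, [], img, lmed=40.0, noise_min_area=4)
        assert out == []


class TestAbbreviations:
    def test_shipped_dictionary_has_at_least_thirty_entries(self):
        table = symbols.load_abbreviations()
        assert len(table) >= 30
        assert table["Me"] == "*C"
        assert all(s.count("*") == 1 for s in table.values())
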