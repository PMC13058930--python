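"""Graph assembly, Molfile serialization and the end-to-end pipeline."""

import math

import numpy as np
import pytest

from ocsr import assemble, fixtures, raster
from ocsr.assemble import Atom, BondEdge, MoleculeGraph
from ocsr.errors import BlankImageError, EmptyGraphError, MolfileError, UnreadableImageError
from ocsr.resolve import ResolvedAtom, ResolvedBond, ResolvedStructure
from ocsr.symbols import ParsedAtom
from ocsr.bonds import BondStyle
from conftest import graphs_isomorphic, hexagon_spec


def _resolved(atoms, bonds):
    ra = [ResolvedAtom(center=p, parsed=ParsedAtom(kind="atom", element=e)) for e, p in atoms]
    rb = [
        ResolvedBond(end1=(0, 0), end2=(1, 1), degree=d, style=BondStyle.SOLID, atom1=i, atom2=j)
        for i, j, d in bonds
    ]
    return ResolvedStructure(atoms=ra, bonds=rb)


class TestConnect:
    def test_two_atoms_one_bond(self):
        g = assemble.connect(_resolved([("C", (0, 0)), ("C", (40, 0))], [(0, 1, 1)]))
        assert len(g.atoms) == 2 and len(g.bonds) == 1

    def test_triangle(self):
        g = assemble.connect(
            _resolved(
                [("C", (0, 0)), ("C", (40, 0)), ("C", (20, 34))],
                [(0, 1, 1), (1, 2, 1), (0, 2, 1)],
            )
        )
        assert len(g.bonds) == 3

    def test_self_loop_dropped(self):
        g = assemble.connect(_resolved([("C", (0, 0)), ("C", (40, 0))], [(0, 0, 1)]))
        assert g.bonds == []

    def test_dangling_bond_dropped(self):
        res = _resolved([("C", (0, 0))], [])
        res.bonds.append(
            ResolvedBond(end1=(0, 0), end2=(1, 1), degree=1, style=BondStyle.SOLID,
                         atom1=0, atom2=None)
        )
        assert assemble.connect(res).bonds == []


class TestLargestComponent:
    def test_noise_fragment_discarded(self):
        g = MoleculeGraph(
            atoms=[Atom("C"), Atom("C"), Atom("C"), Atom("N"), Atom("O")],
            bonds=[BondEdge(0, 1), BondEdge(1, 2), BondEdge(3, 4)],
        )
        out = assemble.largest_component(g)
        assert len(out.atoms) == 3
        assert all(a.element == "C" for a in out.atoms)

    def test_connected_graph_unchanged(self):
        g = MoleculeGraph(atoms=[Atom("C"), Atom("C")], bonds=[BondEdge(0, 1)])
        out = assemble.largest_component(g)
        assert len(out.atoms) == 2

    def test_equal_components_tie_break_is_deterministic(self):
        g = MoleculeGraph(
            atoms=[Atom("C"), Atom("C"), Atom("N"), Atom("N")],
            bonds=[BondEdge(0, 1), BondEdge(2, 3)],
        )
        out1 = assemble.largest_component(g)
        out2 = assemble.largest_component(g)
        assert [a.element for a in out1.atoms] == [a.element for a in out2.atoms] == ["C", "C"]

    def test_empty_graph_rejected(self):
        with pytest.raises(EmptyGraphError):
            assemble.largest_component(MoleculeGraph())


class TestExpandAbbreviations:
    def test_ome_becomes_ether(self):
        g = MoleculeGraph(
            atoms=[Atom("C"), Atom("OMe", is_abbrev=True, pos=(40, 0))],
            bonds=[BondEdge(0, 1)],
        )
        out = assemble.expand_abbreviations(g)
        assert sorted(a.element for a in out.atoms) == ["C", "C", "O"]
        # attachment runs through the oxygen: C-O-C
        nbrs = {}
        for b in out.bonds:
            nbrs.setdefault(b.i, []).append(b.j)
            nbrs.setdefault(b.j, []).append(b.i)
        o_idx = next(i for i, a in enumerate(out.atoms) if a.element == "O")
        assert len(nbrs[o_idx]) == 2

    def test_graph_without_pseudo_atoms_unchanged(self):
        g = MoleculeGraph(atoms=[Atom("C"), Atom("N")], bonds=[BondEdge(0, 1)])
        out = assemble.expand_abbreviations(g)
        assert [a.element for a in out.atoms] == ["C", "N"]

    def test_two_neighbour_pseudo_atom_left_flagged(self):
        g = MoleculeGraph(
            atoms=[Atom("C"), Atom("OMe", is_abbrev=True), Atom("C")],
            bonds=[BondEdge(0, 1), BondEdge(1, 2)],
        )
        out = assemble.expand_abbreviations(g)
        assert "*" in [a.element for a in out.atoms]

    def test_unknown_abbreviation_left_as_star(self):
        g = MoleculeGraph(
            atoms=[Atom("C"), Atom("Xyz", is_abbrev=True)], bonds=[BondEdge(0, 1)]
        )
        out = assemble.expand_abbreviations(g)
        assert [a.element for a in out.atoms] == ["C", "*"]


class TestMolfile:
    def test_single_atom_minimal_molfile(self):
        g = MoleculeGraph(atoms=[Atom("C", pos=(10, 10))])
        text = assemble.write_molfile(g, image_height=100)
        lines = text.splitlines()
        assert lines[3].startswith("  1  0")
        assert lines[3].endswith("V2000")
        assert lines[-1] == "M  END"

    def test_charge_record_present(self):
        g = MoleculeGraph(atoms=[Atom("O", charge=-1, pos=(0, 0))])
        assert "M  CHG  1   1  -1" in assemble.write_molfile(g, 10)

    def test_round_trip_preserves_graph(self):
        g = MoleculeGraph(
            atoms=[Atom("C", pos=(0, 0)), Atom("N", charge=1, pos=(40, 0)), Atom("O", pos=(20, 30))],
            bonds=[BondEdge(0, 1, order=2), BondEdge(1, 2, order=1, aromatic=True)],
        )
        back = assemble.read_molfile(assemble.write_molfile(g, 100))
        assert [a.element for a in back.atoms] == ["C", "N", "O"]
        assert [a.charge for a in back.atoms] == [0, 1, 0]
        assert [(b.i, b.j, b.order, b.aromatic) for b in back.bonds] == [
            (0, 1, 2, False),
            (1, 2, 1, True),
        ]

    def test_external_toolkit_parses_output(self):
        from rdkit import Chem

        g = MoleculeGraph(
            atoms=[Atom("C", pos=(0.0, 0.0)), Atom("C", pos=(40.0, 0.0))],
            bonds=[BondEdge(0, 1, order=1)],
        )
        mol = Chem.MolFromMolBlock(assemble.write_molfile(g, 50))
        assert mol is not None and mol.GetNumAtoms() == 2

    def test_v2000_atom_limit_enforced(self):
        g = MoleculeGraph(atoms=[Atom("C") for _ in range(1000)])
        with pytest.raises(MolfileError):
            assemble.write_molfile(g, 10)

    def test_output_byte_stable(self):
        g = MoleculeGraph(
            atoms=[Atom("C", pos=(0, 0)), Atom("O", pos=(40, 0))], bonds=[BondEdge(0, 1)]
        )
        assert assemble.write_molfile(g, 50) == assemble.write_molfile(g, 50)


class TestRecognize:
    def test_benzene_with_circle_is_isomorphic_to_truth(self):
        spec = hexagon_spec()
        spec.aromatic_circles = [list(range(6))]
        for b in spec.bonds:
            b.aromatic = True
        fx = fixtures.render(spec)
        g, _ = assemble.recognize_graph(fx.image)
        assert graphs_isomorphic(g, spec)

    def test_amide_style_fragment_recognized(self):
        # C-C(=O)-N with explicit N and O labels, one double bond to O
        spec = fixtures.MoleculeSpec(
            atoms=[
                fixtures.AtomSpec(pos=(0.0, 0.0)),
                fixtures.AtomSpec(pos=(0.87, 0.5)),
                fixtures.AtomSpec(element="O", pos=(0.87, 1.5)),
                fixtures.AtomSpec(element="N", hcount=2, pos=(1.73, 0.0)),
            ],
            bonds=[
                fixtures.BondSpec(0, 1),
                fixtures.BondSpec(1, 2, order=2),
                fixtures.BondSpec(1, 3),
            ],
        )
        fx = fixtures.render(spec)
        g, _ = assemble.recognize_graph(fx.image)
        assert graphs_isomorphic(g, spec)

    def test_blank_page_raises_blank_image_error(self):
        with pytest.raises(BlankImageError):
            assemble.recognize(np.full((100, 100), 255, dtype=np.uint8))

    def test_unreadable_file_raises_distinct_error(self, tmp_path):
        path = tmp_path / "not_an_image.png"
        path.write_text("this is not a PNG")
        with pytest.raises(UnreadableImageError):
            assemble.recognize(str(path))

    def test_recognize_is_deterministic(self):
        spec = fixtures.random_spec(7, seed=12)
        fx = fixtures.render(spec)
        assert assemble.recognize(fx.image) == assemble.recognize(fx.image)

    def test_explicit_hydrogens_emitted_in_molfile(self):
        spec = fixtures.MoleculeSpec(
            atoms=[
                fixtures.AtomSpec(pos=(0.0, 0.0)),
                fixtures.AtomSpec(element="N", hcount=2, pos=(1.0, 0.0)),
            ],
            bonds=[fixtures.BondSpec(0, 1)],
        )
        fx = fixtures.render(spec)
        molfile = assemble.recognize(fx.image)
        back = assemble.read_molfile(molfile)
        assert sorted(a.element for a in back.atoms) == ["C", "H", "H", "N"]
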