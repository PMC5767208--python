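"""Structure I/O, channel typing and rigid-body superposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from mrfe import fixtures
from mrfe.structures import (
    Atom,
    ChannelAssignment,
    DegenerateGeometryError,
    LIGAND,
    LigandSelector,
    MolecularComplex,
    RECEPTOR,
    RadiiLookupError,
    RadiiTable,
    StructureFormatError,
    assign_channel,
    read_structure,
    superpose,
    write_structure,
)

HETATM_C = (
    "HETATM    1  C1  LIG A   1       1.000   2.000   3.000  1.00  0.00           C\n"
)


class TestReadStructure:
    def test_single_hetatm_matching_selector_is_ligand(self):
        comp = read_structure(HETATM_C, LigandSelector.by_resname("LIG"))
        assert len(comp) == 1
        atom = comp.atoms[0]
        assert atom.owner == LIGAND
        assert atom.element == "C"
        np.testing.assert_allclose(atom.coords, [1.0, 2.0, 3.0])

    def test_non_matching_selector_maps_to_receptor(self):
        # needs one ligand atom somewhere for the complex invariant
        text = HETATM_C + (
            "HETATM    2  C2  XXX A   2       0.000   0.000   0.000  1.00  0.00           C\n"
        )
        comp = read_structure(text, LigandSelector.by_resname("LIG"))
        owners = [a.owner for a in comp.atoms]
        assert owners == [LIGAND, RECEPTOR]

    def test_unknown_element_raises_lookup_error_naming_it(self):
        text = HETATM_C.replace("           C", "          Xx")
        with pytest.raises(RadiiLookupError, match="Xx"):
            read_structure(text, LigandSelector.by_resname("LIG"))

    def test_corrupt_coordinates_raise_format_error_with_line(self):
        text = HETATM_C.replace("   1.000", "   abc.0")
        with pytest.raises(StructureFormatError, match="line 1"):
            read_structure(text)

    def test_roundtrip_preserves_atoms_to_pdb_precision(self, toy_complex):
        back = read_structure(write_structure(toy_complex))
        assert len(back) == len(toy_complex)
        assert [a.element for a in back.atoms] == [a.element for a in toy_complex.atoms]
        assert [a.owner for a in back.atoms] == [a.owner for a in toy_complex.atoms]
        np.testing.assert_allclose(back.coords, toy_complex.coords, atol=1.5e-3)


CHANNEL_CASES = [
    ("C", RECEPTOR, False, ChannelAssignment(1, +1)),
    ("Cl", RECEPTOR, False, ChannelAssignment(1, +1)),
    ("C", LIGAND, False, ChannelAssignment(1, -1)),
    ("H", LIGAND, True, ChannelAssignment(0, -1)),
    ("H", RECEPTOR, False, None),  # nonpolar hydrogen: no map
    ("N", RECEPTOR, False, ChannelAssignment(2, +1)),
    ("O", LIGAND, False, ChannelAssignment(3, -1)),
    ("F", RECEPTOR, False, ChannelAssignment(3, +1)),
    ("S", LIGAND, False, ChannelAssignment(4, -1)),
    ("P", RECEPTOR, False, ChannelAssignment(4, +1)),
]


class TestChannels:
    @pytest.mark.parametrize("element,owner,polar,expected", CHANNEL_CASES)
    def test_assignment_table(self, radii, element, owner, polar, expected):
        r_ion, r_vdw = radii.lookup(element)
        atom = Atom(element, (0, 0, 0), owner, polar, r_ion, r_vdw)
        assert assign_channel(atom) == expected

    def test_total_on_the_ten_elements_and_sign_follows_ownership(self, radii):
        for el in radii.elements():
            for owner, sign in ((LIGAND, -1), (RECEPTOR, +1)):
                r_ion, r_vdw = radii.lookup(el)
                atom = Atom(el, (0, 0, 0), owner, True, r_ion, r_vdw)
                ca = assign_channel(atom)
                assert ca is not None
                assert ca.sign == sign
                assert 0 <= ca.channel <= 4


class TestRadiiTable:
    def test_default_table_orders_radii(self, radii):
        for el in radii.elements():
            r_ion, r_vdw = radii.lookup(el)
            assert 0 < r_ion < r_vdw

    def test_json_roundtrip_and_override(self):
        table = RadiiTable({"C": (0.5, 1.5)})
        again = RadiiTable.from_json(table.to_json())
        assert again.lookup("C") == (0.5, 1.5)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            RadiiTable({"C": (1.5, 0.5)})


class TestSuperpose:
    def test_identity(self, toy_complex):
        anchors = [(i, i) for i in range(6)]
        moved, rmsd = superpose(toy_complex, toy_complex, anchors)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(moved.coords, toy_complex.coords, atol=1e-9)

    def test_translation_recovered(self, toy_complex):
        shifted = toy_complex.with_coords(toy_complex.coords + np.array([1.0, 2.0, 3.0]))
        moved, rmsd = superpose(shifted, toy_complex, [(i, i) for i in range(6)])
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(moved.coords, toy_complex.coords, atol=1e-9)

    def test_rotation_with_jitter_matches_brute_force_grid_oracle(self, toy_complex):
        rng = np.random.default_rng(5)
        rot90 = Rotation.from_euler("z", 90, degrees=True)
        noisy = rot90.apply(toy_complex.coords) + rng.normal(0, 0.1, toy_complex.coords.shape)
        mobile = toy_complex.with_coords(noisy)
        anchors = [(i, i) for i in range(len(toy_complex))]
        _, rmsd = superpose(mobile, toy_complex, anchors)

        # oracle: two-stage dense search over rotations, optimal translation
        ref = toy_complex.coords - toy_complex.coords.mean(axis=0)
        mob = noisy - noisy.mean(axis=0)

        def scan(center, span, step):
            a = np.arange(center[0] - span, center[0] + span + 1e-9, step)
            b = np.arange(center[1] - span, center[1] + span + 1e-9, step)
            c = np.arange(center[2] - span, center[2] + span + 1e-9, step)
            grid = np.array(np.meshgrid(a, b, c, indexing="ij")).reshape(3, -1).T
            mats = Rotation.from_euler("zyz", grid, degrees=True).as_matrix()
            moved = np.einsum("rij,nj->rni", mats, mob)
            d = np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=2), axis=1))
            i = int(np.argmin(d))
            return grid[i], float(d[i])

        center, _ = scan((180.0, 0.0, 180.0), 180.0, 10.0)
        center, best = scan(center, 10.0, 1.0)
        assert rmsd <= best + 1e-9
        assert rmsd == pytest.approx(best, abs=0.02)

    def test_idempotent(self, toy_complex):
        mobile = toy_complex.with_coords(toy_complex.coords + np.array([3.0, -1.0, 2.0]))
        anchors = [(i, i) for i in range(8)]
        once, _ = superpose(mobile, toy_complex, anchors)
        twice, _ = superpose(once, toy_complex, anchors)
        assert np.abs(twice.coords - once.coords).max() < 1e-9

    def test_too_few_or_collinear_anchors_rejected(self, radii):
        r_ion, r_vdw = radii.lookup("C")
        line = MolecularComplex(
            [Atom("C", (float(i), 0, 0), LIGAND, False, r_ion, r_vdw) for i in range(4)]
        )
        with pytest.raises(DegenerateGeometryError):
            superpose(line, line, [(0, 0), (1, 1)])
        with pytest.raises(DegenerateGeometryError):
            superpose(line, line, [(0, 0), (1, 1), (2, 2), (3, 3)])


def test_selector_default_marks_hetatm_nonsolvent_as_ligand():
    sel = LigandSelector()
    assert sel.is_ligand("ABC", "A", hetero=True)
    assert not sel.is_ligand("HOH", "A", hetero=True)
    assert not sel.is_ligand("ALA", "A", hetero=False)


def test_polar_hydrogen_rule_uses_distance_to_heteroatoms(radii):
    rh = radii.lookup("H")
    ro = radii.lookup("O")
    text = (
        "HETATM    1  O1  LIG A   1       0.000   0.000   0.000  1.00  0.00           O\n"
        "HETATM    2  H1  LIG A   1       0.950   0.000   0.000  1.00  0.00           H\n"
        "HETATM    3  H2  LIG A   1       4.000   0.000   0.000  1.00  0.00           H\n"
    )
    comp = read_structure(text, LigandSelector.by_resname("LIG"))
    polar = [a.is_polar_hydrogen for a in comp.atoms if a.element == "H"]
    assert polar == [True, False]
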