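"""Structure parsing, heavy-atom distances and active-site layer assignment."""

import numpy as np
import pytest

from remotecat.simulate import gen_structure, ligand_moieties
from remotecat.structure import (
    LigandMoiety,
    StructureFormatError,
    RecordError,
    assign_layers,
    distance_report,
    first_layer,
    min_heavy_atom_distance,
    read_structure,
)

PDB_3ATOMS = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       0.000   1.000   0.000  1.00  0.00           C
END
"""

PDB_ALTLOC = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60  0.00           C
END
"""


class TestReadStructure:
    def test_three_atoms(self):
        s = read_structure(PDB_3ATOMS)
        assert len(s) == 3
        np.testing.assert_allclose(
            s.coords, [[0, 0, 0], [1, 0, 0], [0, 1, 0]], atol=1e-6
        )

    @pytest.mark.filterwarnings("ignore:.*heavy atoms")
    def test_altloc_highest_occupancy_wins(self):
        s = read_structure(PDB_ALTLOC)
        assert len(s) == 1
        assert s.atoms[0].altloc == "B"
        assert s.atoms[0].x == pytest.approx(1.0)

    @pytest.mark.filterwarnings("ignore:.*heavy atoms")
    def test_altloc_tie_prefers_first_id(self):
        text = PDB_ALTLOC.replace("0.40", "0.60")
        s = read_structure(text)
        assert s.atoms[0].altloc == "A"

    def test_no_records_is_format_error(self):
        with pytest.raises(StructureFormatError):
            read_structure("HEADER  NOTHING\nEND\n")

    def test_malformed_coordinate_names_line(self):
        bad = PDB_3ATOMS.replace("   1.000   0.000   0.000", "   x.000   0.000   0.000")
        with pytest.raises(RecordError) as err:
            read_structure(bad)
        assert err.value.line_number == 2

    def test_residue_count_matches_text_scan(self):
        """Residue count equals an independent line-scan of distinct
        (chain, residue number) pairs in the raw ATOM records."""
        pdb, _ = gen_structure(layer_plan={1: 3, 2: 2, 3: 1}, n_none=3)
        seen = set()
        for line in pdb.splitlines():
            if line.startswith("ATOM"):
                seen.add((line[21], int(line[22:26])))
        s = read_structure(pdb)
        assert len(s.residue_ids(het=False)) == len(seen)

    def test_chain_filter(self):
        with pytest.raises(StructureFormatError):
            read_structure(PDB_3ATOMS, chain="Z")

    def test_incomplete_residue_warns(self):
        # a lone CA is fewer than half of ALA's 5 heavy atoms
        text = "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\nEND\n"
        with pytest.warns(UserWarning, match="heavy atoms"):
            read_structure(text)


class TestMinHeavyAtomDistance:
    def test_identical_singletons(self, toy_structure):
        s, _ = toy_structure
        a = [s.atoms[0]]
        assert min_heavy_atom_distance(a, a) == 0.0

    def test_3_4_5_triangle(self):
        s = read_structure(PDB_3ATOMS)
        a = [s.atoms[0]._replace() if False else s.atoms[0]]
        b = [s.atoms[1]]
        import dataclasses

        a345 = [dataclasses.replace(s.atoms[0], x=0.0, y=0.0, z=0.0)]
        b345 = [dataclasses.replace(s.atoms[1], x=3.0, y=4.0, z=0.0)]
        assert min_heavy_atom_distance(a345, b345) == pytest.approx(5.0)

    def test_matches_brute_force_and_symmetry(self, rng, toy_structure):
        import dataclasses

        s, _ = toy_structure
        template = s.atoms[0]
        pa = rng.uniform(0, 20, (20, 3))
        pb = rng.uniform(0, 20, (20, 3))
        A = [dataclasses.replace(template, x=p[0], y=p[1], z=p[2]) for p in pa]
        B = [dataclasses.replace(template, x=p[0], y=p[1], z=p[2]) for p in pb]
        expected = min(
            np.linalg.norm(x - y) for x in pa for y in pb
        )
        assert min_heavy_atom_distance(A, B) == pytest.approx(expected, abs=1e-12)
        assert min_heavy_atom_distance(B, A) == pytest.approx(expected, abs=1e-12)

    def test_hydrogens_excluded_and_empty_errors(self, toy_structure):
        import dataclasses

        s, _ = toy_structure
        h = dataclasses.replace(s.atoms[0], element="H")
        with pytest.raises(ValueError):
            min_heavy_atom_distance([h], [s.atoms[0]])


class TestLayers:
    def test_first_layer_includes_contact_residue(self, toy_structure, toy_ligand):
        s, manifest = toy_structure
        fl = first_layer(s, toy_ligand, 4.0)
        planned_first = {num for num, lab in manifest["layers"].items() if lab == 1}
        assert {rid[1] for rid in fl} == planned_first

    def test_first_layer_equals_brute_force(self, toy_structure, toy_ligand):
        s, _ = toy_structure
        fl = first_layer(s, toy_ligand, 4.0)
        brute = {
            rid
            for rid in s.residue_ids(het=False)
            if min_heavy_atom_distance(s.residue_atoms(rid), toy_ligand.atoms) <= 4.0
        }
        assert fl == brute

    def test_linear_chain_layers(self, toy_structure, toy_ligand):
        """Residues placed in consecutive shells get labels 1, 2, 3, none."""
        s, manifest = toy_structure
        fl = first_layer(s, toy_ligand, 4.0)
        assignment = assign_layers(s, fl, 5.0)
        got = {rid[1]: lab for rid, lab in assignment.layers.items()}
        assert got == manifest["layers"]

    def test_lowest_shell_wins(self, toy_structure, toy_ligand):
        """A residue within the shell cutoff of both layer-1 and layer-2
        residues is labelled 2 (the lowest eligible shell)."""
        s, _ = toy_structure
        fl = first_layer(s, toy_ligand, 4.0)
        # with a huge shell cutoff, every non-first residue touches layer 1
        assignment = assign_layers(s, fl, shell_cutoff=100.0)
        labels = set(assignment.layers.values())
        assert 3 not in labels
        assert all(lab in (1, 2) for lab in assignment.layers.values())

    def test_brute_force_oracle(self, toy_structure, toy_ligand):
        """Layer labels equal an independent brute-force shell expansion."""
        s, _ = toy_structure
        fl = first_layer(s, toy_ligand, 4.0)
        assignment = assign_layers(s, fl, 5.0)

        residues = s.residue_ids(het=False)
        dist = {
            (a, b): min_heavy_atom_distance(s.residue_atoms(a), s.residue_atoms(b))
            for a in residues
            for b in residues
        }
        expected = {rid: (1 if rid in fl else None) for rid in residues}
        for level in (2, 3):
            src = {r for r, lab in expected.items() if lab == level - 1}
            for rid in residues:
                if expected[rid] is None and any(dist[(rid, sr)] <= 5.0 for sr in src):
                    expected[rid] = level
        assert assignment.layers == expected

    def test_monotone_in_cutoff(self, toy_structure, toy_ligand):
        """Growing the shell cutoff never removes a residue from layers 1-3."""
        s, _ = toy_structure
        fl = first_layer(s, toy_ligand, 4.0)
        small = assign_layers(s, fl, 4.5)
        in_small = {rid for rid, lab in small.layers.items() if lab is not None}
        big = assign_layers(s, fl, 6.5)
        in_big = {rid for rid, lab in big.layers.items() if lab is not None}
        assert in_small <= in_big

    def test_shell_exclusivity_and_support(self, toy_structure, toy_ligand):
        s, _ = toy_structure
        fl = first_layer(s, toy_ligand, 4.0)
        assignment = assign_layers(s, fl, 5.0)
        l1, l2, l3 = (assignment.in_layer(k) for k in (1, 2, 3))
        assert not (l1 & l2) and not (l1 & l3) and not (l2 & l3)
        for rid in l2:
            assert any(
                min_heavy_atom_distance(s.residue_atoms(rid), s.residue_atoms(o)) <= 5.0
                for o in l1
            )
        for rid in l3:
            assert any(
                min_heavy_atom_distance(s.residue_atoms(rid), s.residue_atoms(o)) <= 5.0
                for o in l2
            )

    def test_atom_order_permutation_invariance(self, toy_structure, rng):
        from remotecat.structure import Structure

        s, manifest = toy_structure
        perm = rng.permutation(len(s.atoms))
        shuffled = Structure([s.atoms[i] for i in perm])
        lig = LigandMoiety("whole-ligand", shuffled.het_atoms())
        fl = first_layer(shuffled, lig, 4.0)
        assignment = assign_layers(shuffled, fl, 5.0)
        assert {rid[1]: lab for rid, lab in assignment.layers.items()} == manifest["layers"]

    def test_empty_first_layer_errors(self, toy_structure):
        s, _ = toy_structure
        with pytest.raises(ValueError):
            assign_layers(s, set(), 5.0)


class TestDistanceReport:
    def test_constructed_distance(self, toy_structure, toy_ligand, toy_moieties):
        s, _ = toy_structure
        fl = first_layer(s, toy_ligand, 4.0)
        assignment = assign_layers(s, fl, 5.0, moieties=toy_moieties)
        report = distance_report(assignment)
        # brute-force recomputation of every row
        for _, row in report.iterrows():
            rid = (row["chain"], row["res_num"])
            moiety = next(m for m in toy_moieties if m.label == row["moiety"])
            d = min_heavy_atom_distance(s.residue_atoms(rid), moiety.atoms)
            assert row["distance"] == pytest.approx(d, abs=1e-12)
            others = [m for m in toy_moieties if m.label != row["moiety"]]
            assert all(
                min_heavy_atom_distance(s.residue_atoms(rid), m.atoms) >= d for m in others
            )

    def test_missing_residue_named(self, toy_structure, toy_ligand, toy_moieties):
        s, _ = toy_structure
        fl = first_layer(s, toy_ligand, 4.0)
        assignment = assign_layers(s, fl, 5.0, moieties=toy_moieties)
        with pytest.raises(KeyError, match="Z:999"):
            distance_report(assignment, residues=[("Z", 999)])
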