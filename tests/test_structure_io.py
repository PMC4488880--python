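"""Reading, assembly expansion and colored-structure writing."""

import math

import numpy as np
import pytest

from capsidprof import (
    CalphaModel,
    InputError,
    ResidueKey,
    RigidTransform,
    StructuralProfile,
    expand_assembly,
    read_structure,
    read_transforms,
    write_colored_structure,
)
from capsidprof.structure_io import read_bfactors

from conftest import pdb_text, random_rigid_transform


def rot_z(deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return [[c, -s, 0], [s, c, 0], [0, 0, 1]]


IDENTITY = ([[1, 0, 0], [0, 1, 0], [0, 0, 1]], [0, 0, 0])


class TestReadStructure:
    def test_minimal_fixture_round_trip(self, three_residue_pdb):
        model = read_structure(three_residue_pdb)
        assert len(model) == 3
        assert model.subunit_ids == ["A0"]
        assert [k.seq_num for k in model.residues] == [1, 2, 3]
        assert [k.aa for k in model.residues] == ["M", "K", "L"]
        np.testing.assert_allclose(model.coords[:, 0], [0.0, 3.8, 7.6])

    def test_deterministic(self, three_residue_pdb):
        a = read_structure(three_residue_pdb)
        b = read_structure(three_residue_pdb)
        assert a.residues == b.residues
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_missing_calpha_skipped_with_warning(self, tmp_path, caplog):
        text = pdb_text([("A", [(1, "M", (0.0, 0, 0)), (3, "L", (7.6, 0, 0))])])
        # residue 2 present but with an N atom only
        lines = text.splitlines()
        lines.insert(2, "ATOM      9  N   LYS A   2       3.800   0.000"
                        "   0.000  1.00  0.00           N")
        path = tmp_path / "gap.pdb"
        path.write_text("\n".join(lines))
        with caplog.at_level("WARNING"):
            model = read_structure(path)
        assert len(model) == 2
        assert "no CA atom" in caplog.text

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "ATOM      1  CA AMET A   1       1.000   0.000   0.000"
            "  0.40  0.00           C\n"
            "ATOM      2  CA BMET A   1       2.000   0.000   0.000"
            "  0.60  0.00           C\n"
            "END\n"
        )
        model = read_structure(path)
        assert len(model) == 1
        assert model.coords[0, 0] == pytest.approx(2.0)

    def test_waters_and_ligands_excluded(self, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(
            "ATOM      1  CA  MET A   1       1.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "HETATM    2  O   HOH A 101       5.000   0.000   0.000"
            "  1.00  0.00           O\n"
            "END\n"
        )
        assert len(read_structure(path)) == 1

    def test_empty_model_is_input_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HETATM    1  O   HOH A   1       0.000   0.000"
                        "   0.000  1.00  0.00           O\nEND\n")
        with pytest.raises(InputError):
            read_structure(path)

    def test_unknown_assembly_is_input_error(self, three_residue_pdb):
        with pytest.raises(InputError, match="assembly"):
            read_structure(three_residue_pdb, assembly="9")

    def test_missing_file(self, tmp_path):
        with pytest.raises(InputError, match="not found"):
            read_structure(tmp_path / "nope.pdb")

    def test_biomt_expansion_counts(self, tmp_path):
        """1 chain x 10 residues under 60 operators -> 600 residues."""
        ops = [IDENTITY] + [
            (rot_z(6 * k), [0, 0, float(k)]) for k in range(1, 60)
        ]
        residues = [(i + 1, "A", (10.0 + i, 0.0, 0.0)) for i in range(10)]
        path = tmp_path / "cap.pdb"
        path.write_text(pdb_text([("A", residues)], biomt_ops=ops))
        model = read_structure(path, assembly="1")
        assert len(model) == 600
        assert len(model.subunits) == 60
        assert model.subunit_ids[:3] == ["A0", "A1", "A2"]
        # asu read is unaffected
        assert len(read_structure(path, assembly="asu")) == 10


class TestExpandAssembly:
    def test_identity_only_is_noop_on_coordinates(self, collinear_model):
        out = expand_assembly(collinear_model, [RigidTransform.identity()])
        np.testing.assert_array_equal(out.coords, collinear_model.coords)
        assert len(out.subunits) == len(collinear_model.subunits)

    def test_180_degree_rotation_about_z(self):
        model = CalphaModel(
            [ResidueKey("A0", "A", 1, "", "A"),
             ResidueKey("A0", "A", 2, "", "A")],
            np.array([[1.0, 0, 0], [0.0, 1, 0]]),
        )
        tr = RigidTransform(np.array(rot_z(180.0)), np.zeros(3))
        out = expand_assembly(model, [tr])
        np.testing.assert_allclose(out.coords[0], [-1, 0, 0], atol=1e-12)

    def test_rigid_motion_preserves_distances(self, collinear_model):
        rng = np.random.default_rng(0)
        rot, tra = random_rigid_transform(rng)
        out = expand_assembly(collinear_model, [RigidTransform(rot, tra)])
        orig = np.linalg.norm(
            collinear_model.coords[:, None] - collinear_model.coords[None], axis=-1)
        new = np.linalg.norm(out.coords[:, None] - out.coords[None], axis=-1)
        np.testing.assert_allclose(new, orig, atol=1e-9)

    def test_inverse_recovers_coordinates(self, small_capsid):
        rng = np.random.default_rng(1)
        rot, tra = random_rigid_transform(rng)
        tr = RigidTransform(rot, tra)
        moved = expand_assembly(small_capsid, [tr])
        back = expand_assembly(moved, [tr.inverse()])
        np.testing.assert_allclose(back.coords, small_capsid.coords, atol=1e-9)

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(InputError, match="orthonormal"):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_improper_rotation_rejected(self):
        with pytest.raises(InputError, match="determinant"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_empty_transform_list_rejected(self, collinear_model):
        with pytest.raises(InputError):
            expand_assembly(collinear_model, [])

    def test_transform_major_chain_minor_order(self):
        model = CalphaModel(
            [ResidueKey("A0", "A", 1, "", "A"),
             ResidueKey("B0", "B", 1, "", "A")],
            np.array([[0.0, 0, 0], [5.0, 0, 0]]),
        )
        out = expand_assembly(
            model, [RigidTransform.identity(),
                    RigidTransform(np.eye(3), np.array([0.0, 0, 9]))])
        assert [k.subunit_id for k in out.residues] == ["A0", "B0", "A1", "B1"]


class TestOperatorFile:
    def test_read_transforms(self, tmp_path):
        path = tmp_path / "ops.txt"
        path.write_text("# identity then z-shift\n"
                        "1 0 0 0 1 0 0 0 1 0 0 0\n"
                        "1 0 0 0 1 0 0 0 1 0 0 7.5\n")
        trs = read_transforms(path)
        assert len(trs) == 2
        np.testing.assert_allclose(trs[1].translation, [0, 0, 7.5])

    def test_bad_row(self, tmp_path):
        path = tmp_path / "ops.txt"
        path.write_text("1 0 0 0 1 0 0 0 1 0 0\n")
        with pytest.raises(InputError, match="12 numbers"):
            read_transforms(path)


class TestColoredWrite:
    def _profile(self, model, values):
        return StructuralProfile(list(model.residues), np.asarray(values),
                                 kind="normalized")

    def test_bfactor_round_trip_two_decimals(self, three_residue_pdb, tmp_path):
        model = read_structure(three_residue_pdb)
        prof = self._profile(model, [-1.5, 0.0, 2.25])
        out = tmp_path / "colored.pdb"
        write_colored_structure(model, prof, out, mode="pdb_bfactor")
        b = read_bfactors(out)
        assert b[("A", 1, "")] == pytest.approx(-1.50, abs=1e-9)
        assert b[("A", 2, "")] == pytest.approx(0.00, abs=1e-9)
        assert b[("A", 3, "")] == pytest.approx(2.25, abs=1e-9)

    def test_constant_profile(self, three_residue_pdb, tmp_path):
        model = read_structure(three_residue_pdb)
        out = tmp_path / "c.pdb"
        write_colored_structure(model, self._profile(model, [1.0] * 3), out)
        assert all(v == pytest.approx(1.0) for v in read_bfactors(out).values())

    def test_foreign_residues_rejected(self, three_residue_pdb, tmp_path):
        model = read_structure(three_residue_pdb)
        alien = StructuralProfile(
            [ResidueKey("Z0", "Z", 99, "", "A")], np.array([1.0]),
            kind="normalized")
        with pytest.raises(InputError, match="absent"):
            write_colored_structure(model, alien, tmp_path / "x.pdb")

    def test_unvalued_residues_get_zero(self, three_residue_pdb, tmp_path):
        model = read_structure(three_residue_pdb)
        prof = StructuralProfile([model.residues[0]], np.array([3.5]),
                                 kind="normalized")
        out = tmp_path / "p.pdb"
        write_colored_structure(model, prof, out)
        b = read_bfactors(out)
        assert b[("A", 1, "")] == pytest.approx(3.5)
        assert b[("A", 2, "")] == pytest.approx(0.0)

    def test_out_of_range_values_clamped(self, three_residue_pdb, tmp_path, caplog):
        model = read_structure(three_residue_pdb)
        prof = self._profile(model, [-500.0, 0.0, 5000.0])
        out = tmp_path / "clamp.pdb"
        with caplog.at_level("WARNING"):
            write_colored_structure(model, prof, out)
        assert "clamped" in caplog.text
        b = read_bfactors(out)
        assert b[("A", 1, "")] == pytest.approx(-99.99)
        assert b[("A", 3, "")] == pytest.approx(999.99)

    def test_attribute_table(self, three_residue_pdb, tmp_path):
        model = read_structure(three_residue_pdb)
        out = tmp_path / "attrs.tsv"
        write_colored_structure(model, self._profile(model, [0.1, 0.2, 0.3]),
                                out, mode="attribute_table")
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == ["subunit", "seq_num", "icode", "value"]
        assert lines[1].startswith("A0\t1\t\t0.1")
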