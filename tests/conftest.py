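"""Shared fixtures: tiny hand-built PDB texts and small synthetic capsids."""

import numpy as np
import pytest

from capsidprof import CalphaModel, ResidueKey, ShellSpec, make_shell_capsid

AA3 = {"A": "ALA", "M": "MET", "K": "LYS", "L": "LEU", "G": "GLY"}


def pdb_text(chains, biomt_ops=None):
    """Render a minimal PDB string.

    chains: list of (chain_id, [(seq_num, aa_letter, (x, y, z)), ...])
    biomt_ops: optional list of (R 3x3 nested list, t 3-list) written as a
        REMARK 350 biological assembly applying to all chains.
    """
    lines = []
    if biomt_ops:
        ids = ", ".join(cid for cid, _ in chains)
        lines.append("REMARK 350 BIOMOLECULE: 1")
        lines.append(f"REMARK 350 APPLY THE FOLLOWING TO CHAINS: {ids}")
        for op_idx, (rot, tra) in enumerate(biomt_ops, 1):
            for row in range(3):
                r = rot[row]
                lines.append(
                    f"REMARK 350   BIOMT{row + 1} {op_idx:3d}"
                    f"{r[0]:10.6f}{r[1]:10.6f}{r[2]:10.6f}"
                    f"{tra[row]:15.5f}"
                )
    serial = 0
    for chain_id, residues in chains:
        for seq_num, aa, (x, y, z) in residues:
            serial += 1
            lines.append(
                f"ATOM  {serial:5d}  CA  {AA3[aa]} {chain_id}{seq_num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        lines.append("TER")
    lines += ["END", ""]
    return "\n".join(lines)


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(pdb_text(
        [("A", [(1, "M", (0.0, 0.0, 0.0)),
                (2, "K", (3.8, 0.0, 0.0)),
                (3, "L", (7.6, 0.0, 0.0))])]
    ))
    return path


@pytest.fixture
def collinear_model():
    """Cα atoms at x = 0, 1, 2 Å: the hand-computed WCN example."""
    keys = [ResidueKey("A0", "A", i + 1, "", "A") for i in range(3)]
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    return CalphaModel(keys, coords)


@pytest.fixture(scope="session")
def small_capsid():
    """12 subunits x 40 residues on one jittered 60 Å shell."""
    return make_shell_capsid(
        ShellSpec(n_subunits=12, residues_per_subunit=40,
                  radii=(60.0,), radial_jitter_sd=1.5, seed=11)
    )


@pytest.fixture(scope="session")
def two_shell_capsid():
    """Equal point counts on radii R and 2R (8 subunits x 50 residues)."""
    return make_shell_capsid(
        ShellSpec(n_subunits=8, residues_per_subunit=50,
                  radii=(40.0, 80.0), radial_jitter_sd=0.5, seed=5)
    )


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a translation."""
    from scipy.stats import special_ortho_group

    rot = special_ortho_group.rvs(3, random_state=rng)
    return rot, rng.uniform(-50, 50, 3)
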