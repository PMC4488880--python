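"""Read and write Cα-only capsid structures.

Structures are reduced to one point per residue (the Cα atom).  A
:class:`CalphaModel` holds the ordered residues of one or more *subunits* —
assembly instances of a chain, identified by the author chain id plus a
transform index (chain ``A`` under transform 0 is subunit ``A0``).  Reading
an asymmetric unit yields transform index 0 for every chain; expanding a
biological assembly replicates the chains under the stored rigid-body
operators, so a 60-operator icosahedral deposition with one chain becomes
subunits ``A0`` … ``A59``.

Parsing is delegated to gemmi (PDB and mmCIF, including the assembly
operators of REMARK 350 / ``_pdbx_struct_assembly_gen``).  Writing is a
minimal Cα-only PDB in which the B-factor column carries an arbitrary
per-residue score, the convention used by molecular viewers for coloring.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

#: letters accepted in ResidueKey.aa
_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")


def _one_letter(resname: str) -> str | None:
    """One-letter code for a residue name, X for nonstandard amino acids,
    None for things that are not amino acids at all (waters, ligands)."""
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return None
    letter = info.one_letter_code.upper()
    return letter if letter in _AA_LETTERS else "X"


@dataclass(frozen=True)
class ResidueKey:
    """Stable identity of one residue within a (possibly expanded) model."""

    subunit_id: str   # chain id + transform index, e.g. "A0"
    chain_id: str     # author chain id
    seq_num: int      # author residue number
    icode: str        # insertion code, "" when blank
    aa: str           # one-letter amino acid, X for nonstandard

    def __post_init__(self) -> None:
        if self.aa not in _AA_LETTERS:
            raise InputError(f"invalid amino-acid letter {self.aa!r}")


@dataclass
class CalphaModel:
    """Ordered Cα-only model; coordinates in Å.

    ``subunits`` maps each subunit id to the contiguous index range of its
    residues, in model order.
    """

    residues: list[ResidueKey]
    coords: np.ndarray                      # (N, 3) float64
    source: str = ""
    subunits: dict[str, range] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.residues) < 1:
            raise InputError("model must contain at least one residue")
        if self.coords.shape != (len(self.residues), 3):
            raise InputError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.residues)} residues"
            )
        if not np.all(np.isfinite(self.coords)):
            raise InputError("non-finite coordinates in model")
        if not self.subunits:
            self.subunits = _infer_subunits(self.residues)
        seen = set()
        for key in self.residues:
            ident = (key.subunit_id, key.seq_num, key.icode)
            if ident in seen:
                raise InputError(f"duplicate residue {ident} in model")
            seen.add(ident)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def subunit_ids(self) -> list[str]:
        return list(self.subunits)

    def subunit_indices(self, subunit: str) -> np.ndarray:
        """Indices of the residues of one subunit, or of all residues."""
        if subunit == "all":
            return np.arange(len(self.residues))
        if subunit not in self.subunits:
            raise InputError(
                f"subunit {subunit!r} not in model "
                f"(available: {', '.join(self.subunit_ids[:8])}"
                f"{', ...' if len(self.subunits) > 8 else ''})"
            )
        return np.asarray(self.subunits[subunit])

    def index_of(self, key: ResidueKey) -> int:
        try:
            return self._index[key]
        except AttributeError:
            self._index = {k: i for i, k in enumerate(self.residues)}
            return self._index[key]


def _infer_subunits(residues: list[ResidueKey]) -> dict[str, range]:
    subunits: dict[str, range] = {}
    start = 0
    for i in range(1, len(residues) + 1):
        if i == len(residues) or residues[i].subunit_id != residues[start].subunit_id:
            sid = residues[start].subunit_id
            if sid in subunits:
                raise InputError(f"subunit {sid!r} is not contiguous in model")
            subunits[sid] = range(start, i)
            start = i
    return subunits


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body motion x' = R·x + t (Å)."""

    rotation: np.ndarray     # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        r = self.rotation
        if r.shape != (3, 3) or self.translation.shape != (3,):
            raise InputError("rigid transform must be a 3x3 rotation and 3-vector")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-6):
            raise InputError("rotation matrix is not orthonormal")
        if np.linalg.det(r) < 0:
            raise InputError("rotation matrix has negative determinant (improper)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


# ---------------------------------------------------------------------------
# reading

def read_structure(
    path: str | os.PathLike,
    format: str = "auto",
    assembly: str | None = "asu",
) -> CalphaModel:
    """Read a PDB/mmCIF file into a Cα-only model.

    Parameters
    ----------
    path : str
        Structure file.
    format : {"auto", "pdb", "mmcif"}
        File format; "auto" detects from content/extension.
    assembly : str or None
        ``"asu"`` (or None) returns the deposited coordinates; an assembly
        id (e.g. ``"1"``) expands the named biological assembly with the
        file's stored operators.

    Notes
    -----
    Residues lacking a Cα atom are skipped with a warning.  For alternate
    locations the highest-occupancy Cα is used (ties: first listed).
    Waters and non-amino-acid ligands are excluded.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"structure file not found: {path}")
    fmt = {"auto": gemmi.CoorFormat.Detect,
           "pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif}.get(format)
    if fmt is None:
        raise InputError(f"unknown structure format {format!r}")
    try:
        st = gemmi.read_structure(path, format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise InputError(f"no models in {path}")
    model = st[0]

    residues: list[ResidueKey] = []
    coords: list[tuple[float, float, float]] = []
    for chain in model:
        for res in chain:
            aa = _one_letter(res.name)
            if aa is None:
                continue
            ca = _pick_calpha(res)
            if ca is None:
                logger.warning(
                    "residue %s %s%d%s has no CA atom; skipped",
                    res.name, chain.name, res.seqid.num, res.seqid.icode.strip(),
                )
                continue
            residues.append(ResidueKey(
                subunit_id=f"{chain.name}0",
                chain_id=chain.name,
                seq_num=res.seqid.num,
                icode=res.seqid.icode.strip(),
                aa=aa,
            ))
            coords.append((ca.pos.x, ca.pos.y, ca.pos.z))
    if not residues:
        raise InputError(f"no Cα atoms found in {path}")

    base = CalphaModel(residues, np.array(coords, dtype=float),
                       source=f"{path} (asu)")
    if assembly in (None, "asu"):
        return base
    return _expand_named_assembly(st, base, assembly, path)


def _pick_calpha(res: gemmi.Residue) -> gemmi.Atom | None:
    best = None
    for atom in res:
        if atom.name != "CA" or atom.element == gemmi.Element("Ca"):
            continue
        if best is None or atom.occ > best.occ:
            best = atom
    return best


def _expand_named_assembly(
    st: gemmi.Structure, base: CalphaModel, assembly: str, path: str
) -> CalphaModel:
    asm = next((a for a in st.assemblies if a.name == str(assembly)), None)
    if asm is None:
        available = ", ".join(a.name for a in st.assemblies) or "none"
        raise InputError(
            f"assembly {assembly!r} not found in {path} (available: {available})"
        )
    parts: list[CalphaModel] = []
    t_offset = 0
    for gen in asm.generators:
        chains = set(gen.chains) | set(gen.subchains)
        if gen.chains:
            idx = [i for i, k in enumerate(base.residues) if k.chain_id in chains]
            if not idx:
                continue
            sub = CalphaModel(
                [base.residues[i] for i in idx], base.coords[idx], base.source
            )
        else:  # generator without explicit chain list applies to everything
            sub = base
        transforms = [
            RigidTransform(np.array(op.transform.mat.tolist()),
                           np.array(op.transform.vec.tolist()))
            for op in gen.operators
        ]
        parts.append(expand_assembly(sub, transforms, transform_offset=t_offset))
        t_offset += len(transforms)
    if not parts:
        raise InputError(f"assembly {assembly!r} in {path} selects no residues")
    residues = [k for p in parts for k in p.residues]
    coords = np.vstack([p.coords for p in parts])
    return CalphaModel(residues, coords, source=f"{path} (assembly {assembly})")


def read_transforms(path: str | os.PathLike) -> list[RigidTransform]:
    """Read rigid transforms from a plain text operator file.

    Each non-comment line holds 12 numbers: the rotation matrix in row-major
    order followed by the translation vector (Å).
    """
    transforms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                vals = [float(tok) for tok in line.split()]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric token") from exc
            if len(vals) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 numbers, got {len(vals)}"
                )
            transforms.append(RigidTransform(
                np.array(vals[:9]).reshape(3, 3), np.array(vals[9:])
            ))
    if not transforms:
        raise InputError(f"no transforms in {path}")
    return transforms


# ---------------------------------------------------------------------------
# assembly expansion

def expand_assembly(
    model: CalphaModel,
    transforms: list[RigidTransform],
    transform_offset: int = 0,
) -> CalphaModel:
    """Replicate every subunit of *model* under each rigid transform.

    Output ordering is transform-major, chain-minor; subunit ids encode
    the chain and the (0-based) transform index.
    """
    if not transforms:
        raise InputError("transform list is empty")
    for tr in transforms:
        if not isinstance(tr, RigidTransform):
            raise InputError("transforms must be RigidTransform instances")

    chain_ids = [k.chain_id for k in model.residues]
    unique_chains = len(set(chain_ids)) == len(model.subunits)

    residues: list[ResidueKey] = []
    blocks: list[np.ndarray] = []
    for t_local, tr in enumerate(transforms):
        t_idx = transform_offset + t_local
        blocks.append(tr.apply(model.coords))
        for key in model.residues:
            base = key.chain_id if unique_chains else key.subunit_id
            residues.append(ResidueKey(
                subunit_id=f"{base}{t_idx}",
                chain_id=key.chain_id,
                seq_num=key.seq_num,
                icode=key.icode,
                aa=key.aa,
            ))
    return CalphaModel(residues, np.vstack(blocks),
                       source=f"{model.source} x{len(transforms)} transforms")


# ---------------------------------------------------------------------------
# writing

#: representable range of the fixed-width %6.2f B-factor field
_BF_MIN, _BF_MAX = -99.99, 999.99

# 62 single-character chain ids usable in the classic PDB chain column
PDB_CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


def write_calpha_pdb(model: CalphaModel, path: str | os.PathLike,
                     bfactors: np.ndarray | None = None) -> None:
    """Write the model as a Cα-only PDB file.

    Chain column carries the author chain id (must be one character);
    the segment id columns carry the full subunit id.
    """
    if bfactors is None:
        bfactors = np.zeros(len(model))
    lines = []
    serial = 0
    prev_subunit = None
    for key, (x, y, z), b in zip(model.residues, model.coords, bfactors):
        if len(key.chain_id) != 1:
            raise InputError(
                f"chain id {key.chain_id!r} does not fit the PDB chain column"
            )
        if prev_subunit is not None and key.subunit_id != prev_subunit:
            lines.append("TER")
        prev_subunit = key.subunit_id
        serial += 1
        resname = _THREE_LETTER.get(key.aa, "UNK")
        lines.append(
            f"ATOM  {min(serial, 99999):5d}  CA  {resname} {key.chain_id}"
            f"{key.seq_num:4d}{key.icode or ' '}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}      "
            f"{key.subunit_id:<4.4s} C"
        )
    lines += ["TER", "END", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def write_colored_structure(model, profile, path, mode: str = "pdb_bfactor") -> None:
    """Write *model* with per-residue scores from *profile* for viewer coloring.

    ``pdb_bfactor`` writes a Cα-only PDB whose B-factor column carries the
    profile value (fixed-width %6.2f; out-of-range values are clamped with a
    log message).  ``attribute_table`` writes a tab-separated per-residue
    table (subunit, seq_num, icode, value).  Model residues without a
    profile value get 0.00 and are logged.
    """
    value_by_key = dict(zip(profile.keys, profile.values))
    model_keys = set(model.residues)
    missing = [k for k in profile.keys if k not in model_keys]
    if missing:
        raise InputError(
            f"profile references {len(missing)} residues absent from the model "
            f"(first: {missing[0]})"
        )

    values = np.zeros(len(model))
    n_unvalued = 0
    for i, key in enumerate(model.residues):
        if key in value_by_key:
            values[i] = value_by_key[key]
        else:
            n_unvalued += 1
    if n_unvalued:
        logger.info("%d model residues have no profile value; set to 0.00",
                    n_unvalued)

    if mode == "pdb_bfactor":
        clamped = np.clip(values, _BF_MIN, _BF_MAX)
        n_clamped = int(np.sum(clamped != values))
        if n_clamped:
            logger.warning("%d values clamped to the B-factor field range "
                           "[%.2f, %.2f]", n_clamped, _BF_MIN, _BF_MAX)
        write_calpha_pdb(model, path, bfactors=clamped)
    elif mode == "attribute_table":
        with open(path, "w") as fh:
            fh.write("subunit\tseq_num\ticode\tvalue\n")
            for key, v in zip(model.residues, values):
                fh.write(f"{key.subunit_id}\t{key.seq_num}\t{key.icode}\t{v:.6f}\n")
    else:
        raise InputError(f"unknown coloring mode {mode!r}")


def read_bfactors(path: str | os.PathLike) -> dict[tuple[str, int, str], float]:
    """Read back per-residue Cα B-factors keyed by (chain, seq_num, icode)."""
    st = gemmi.read_structure(os.fspath(path))
    out = {}
    for chain in st[0]:
        for res in chain:
            ca = _pick_calpha(res)
            if ca is not None:
                out[(chain.name, res.seqid.num, res.seqid.icode.strip())] = ca.b_iso
    return out


def file_sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()
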