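"""Synthetic capsid-like structures and conservation profiles.

Real icosahedral capsids are multi-subunit, roughly spherical protein
shells ~200–1000 Å across.  The generator emulates their gross geometry —
quasi-uniformly spaced Cα points on one or more concentric spherical
shells with Gaussian radial jitter, partitioned into contiguous "chains" —
without any protein-fold realism.  Points are placed with a deterministic
Fibonacci spiral, so neighboring residues along a chain are also spatial
neighbors, as along a real polypeptide.

Synthetic conservation scores are generated as a stated linear function of
a structural z-profile plus Gaussian noise:

    score_i = slope · z_i + ε_i,   ε ~ N(0, σ²)

Because z has unit variance, the population correlation between score and
z has the closed form ρ = slope / √(slope² + σ²) (= 1/√(1+σ²) for unit
slope), which makes the whole pipeline testable against known ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .conservation import ConservationProfile
from .errors import GenerationError, InputError
from .profiles import cdistance_profile, normalize, wcn_profile
from .structure_io import PDB_CHAIN_ALPHABET, CalphaModel, ResidueKey

#: minimum Cα–Cα separation (Å); keeps the inverse-square sum well-conditioned
MIN_SEPARATION = 1.0

_AA_CYCLE = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ShellSpec:
    """Geometry of a synthetic shell capsid."""

    n_subunits: int
    residues_per_subunit: int
    radii: tuple[float, ...] = (100.0,)
    radial_jitter_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "radii", tuple(float(r) for r in self.radii))
        if self.n_subunits < 1 or self.residues_per_subunit < 1:
            raise InputError("subunit and residue counts must be positive")
        if not self.radii or any(r <= 0 for r in self.radii):
            raise InputError("shell radii must be strictly positive")
        if any(b <= a for a, b in zip(self.radii, self.radii[1:])):
            raise InputError("shell radii must be strictly increasing")
        if self.radial_jitter_sd < 0:
            raise InputError("radial jitter sd must be >= 0")


@dataclass(frozen=True)
class SynthConsSpec:
    """Ground-truth link between structure and synthetic conservation."""

    basis: str = "wcn"        # which structural z-profile drives conservation
    slope: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.basis not in ("wcn", "cdist"):
            raise InputError(f"basis must be 'wcn' or 'cdist', got {self.basis!r}")
        if self.noise_sd < 0:
            raise InputError("noise sd must be >= 0")


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors along the Fibonacci (golden-angle) spiral."""
    i = np.arange(n, dtype=float)
    golden = (1 + 5 ** 0.5) / 2
    theta = 2 * np.pi * i / golden
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_shell_capsid(spec: ShellSpec) -> CalphaModel:
    """Build a multi-subunit spherical-shell Cα model.

    Residues are distributed as evenly as possible across the shells
    (inner shells get the remainder first), placed on a Fibonacci spiral
    per shell, radially jittered, and partitioned shell-major into
    ``n_subunits`` contiguous chains.  A minimum Cα separation of 1 Å is
    enforced by re-drawing the jitter of violating points.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_subunits * spec.residues_per_subunit
    n_shells = len(spec.radii)
    per_shell = [n_total // n_shells] * n_shells
    for s in range(n_total % n_shells):
        per_shell[s] += 1

    blocks = []
    for radius, n_pts in zip(spec.radii, per_shell):
        unit = fibonacci_sphere(n_pts)
        r_eff = radius + rng.normal(0.0, spec.radial_jitter_sd, size=n_pts)
        blocks.append((unit, r_eff, radius))

    coords = np.vstack([u * r[:, None] for u, r, _ in blocks])
    for attempt in range(50):
        tree = cKDTree(coords)
        close = tree.query_pairs(MIN_SEPARATION, output_type="ndarray")
        if len(close) == 0:
            break
        bad = np.unique(close.ravel())
        offsets = np.cumsum([0] + [len(u) for u, _, _ in blocks])
        for idx in bad:
            s = int(np.searchsorted(offsets, idx, side="right")) - 1
            unit, _, radius = blocks[s]
            local = idx - offsets[s]
            r_new = radius + rng.normal(0.0, spec.radial_jitter_sd)
            coords[idx] = unit[local] * r_new
    else:
        raise GenerationError(
            f"cannot satisfy the {MIN_SEPARATION} Å minimum separation for "
            f"{n_total} residues on radii {spec.radii}; reduce the density"
        )

    residues = []
    for s in range(spec.n_subunits):
        chain = _chain_id(s)
        for j in range(spec.residues_per_subunit):
            residues.append(ResidueKey(
                subunit_id=f"{chain}0",
                chain_id=chain,
                seq_num=j + 1,
                icode="",
                aa=_AA_CYCLE[j % len(_AA_CYCLE)],
            ))
    return CalphaModel(
        residues, coords,
        source=(f"synthetic shell capsid: {spec.n_subunits}x"
                f"{spec.residues_per_subunit}, radii={spec.radii}, "
                f"jitter={spec.radial_jitter_sd}, seed={spec.seed}"),
    )


def _chain_id(index: int) -> str:
    n = len(PDB_CHAIN_ALPHABET)
    if index < n:
        return PDB_CHAIN_ALPHABET[index]
    return PDB_CHAIN_ALPHABET[index // n - 1] + PDB_CHAIN_ALPHABET[index % n]


def make_conservation(model: CalphaModel, subunit: str,
                      spec: SynthConsSpec) -> ConservationProfile:
    """Synthetic conservation: slope · z_basis + Gaussian noise.

    The basis z-profile is computed for *subunit* in whole-model context
    and z-normalized over that subunit, so with unit slope the population
    correlation between the scores and the basis is 1/√(1 + σ²).
    """
    basis_fn = wcn_profile if spec.basis == "wcn" else cdistance_profile
    z = normalize(basis_fn(model, subunit))
    rng = np.random.default_rng(spec.seed)
    scores = spec.slope * z.values + rng.normal(0.0, spec.noise_sd, len(z))
    return ConservationProfile(
        positions=np.array([k.seq_num for k in z.keys]),
        aas=[k.aa for k in z.keys],
        scores=scores,
    )


def noise_sd_for_rho(rho: float, slope: float = 1.0) -> float:
    """Noise σ giving population correlation ρ = slope/√(slope² + σ²)."""
    if not 0 < rho <= 1:
        raise InputError("rho must be in (0, 1]")
    return abs(slope) * np.sqrt(1.0 / rho ** 2 - 1.0)
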