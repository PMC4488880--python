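"""Per-residue structural profiles: packing density (WCN) and centroid distance.

Two structure-derived quantities are computed from Cα coordinates, each in
whole-capsid context:

* **Weighted contact number (WCN).**  The packing density of residue *i* is
  the cutoff-free inverse-square contact sum

      n_i = Σ_{j ≠ i} 1 / r_ij²

  over *all* residues of the model, where r_ij is the Cα–Cα distance in Å.
  The profile value is its reciprocal, w_i = 1 / n_i, so a *large* w means a
  *loosely* packed residue.  No cutoff radius and no neighbor-list
  approximation is applied anywhere: the sum is exact.

* **Centroid distance (c-distance).**  The Euclidean distance from each Cα
  to the unweighted mean position of all Cα atoms of the model, in Å.

Both profiles can be requested for a single subunit while the sums/centroid
still run over the whole model, which is how multi-subunit shells such as
icosahedral capsids must be treated: the packing of a subunit includes
contributions from its neighbors.

Profiles are z-normalized (mean 0, standard deviation 1, population
divisor) before comparison with conservation profiles, and conservation
profiles may additionally be smoothed with a centered sliding-window mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import DegenerateGeometryError, DegenerateProfileError, InputError
from .structure_io import CalphaModel, ResidueKey

#: Cα pairs closer than this (Å) make the inverse-square sum singular
COINCIDENT_TOL = 1e-6

#: profile kinds
WCN_RAW = "wcn_raw"          # w_i = 1/n_i, Å² per residue
CDIST_RAW = "cdist_raw"      # Å
NORMALIZED = "normalized"    # dimensionless z
CONSERVATION = "conservation"

_VALID_KINDS = {WCN_RAW, CDIST_RAW, NORMALIZED, CONSERVATION}


@dataclass
class StructuralProfile:
    """A per-residue numeric series for one subunit (or the whole model)."""

    keys: list[ResidueKey]
    values: np.ndarray
    kind: str
    context: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in _VALID_KINDS:
            raise InputError(f"unknown profile kind {self.kind!r}")
        if len(self.keys) != len(self.values):
            raise InputError("profile keys and values differ in length")
        if not np.all(np.isfinite(self.values)):
            raise InputError("non-finite profile values")
        if self.kind == WCN_RAW and not np.all(self.values > 0):
            raise InputError("raw WCN values must be strictly positive")

    def __len__(self) -> int:
        return len(self.keys)


# ---------------------------------------------------------------------------
# WCN

def wcn_profile(model: CalphaModel, subunit: str = "all",
                block_size: int = 2048) -> StructuralProfile:
    """Reciprocal packing density w_i = 1/n_i for the requested subunit.

    The contact sum n_i runs over every residue of *model* regardless of
    which subunit is requested.  Computation is exact; blocking only bounds
    memory for large capsids.
    """
    if len(model) < 2:
        raise InputError("WCN requires a model with at least 2 residues")
    rows = model.subunit_indices(subunit)
    coords = model.coords
    n = np.empty(len(rows))
    tol2 = COINCIDENT_TOL ** 2
    for start in range(0, len(rows), block_size):
        block = rows[start:start + block_size]
        d2 = cdist(coords[block], coords, metric="sqeuclidean")
        d2[np.arange(len(block)), block] = np.inf  # exclude j == i
        bad = np.argwhere(d2 < tol2)
        if bad.size:
            bi, j = bad[0]
            i = block[bi]
            raise DegenerateGeometryError(
                f"coincident Cα pair: {model.residues[i]} and {model.residues[j]} "
                f"are closer than {COINCIDENT_TOL} Å"
            )
        n[start:start + len(block)] = np.sum(1.0 / d2, axis=1)
    return StructuralProfile(
        keys=[model.residues[i] for i in rows],
        values=1.0 / n,
        kind=WCN_RAW,
        context=f"whole model, {len(model)} residues, subunit={subunit}",
    )


# ---------------------------------------------------------------------------
# centroid distance

def cdistance_profile(model: CalphaModel, subunit: str = "all") -> StructuralProfile:
    """Distance (Å) from each Cα of the subunit to the whole-model centroid."""
    rows = model.subunit_indices(subunit)
    centroid = model.coords.mean(axis=0)
    dist = np.linalg.norm(model.coords[rows] - centroid, axis=1)
    return StructuralProfile(
        keys=[model.residues[i] for i in rows],
        values=dist,
        kind=CDIST_RAW,
        context=f"whole model, {len(model)} residues, subunit={subunit}",
    )


# ---------------------------------------------------------------------------
# normalization and smoothing

def znorm(values: np.ndarray) -> np.ndarray:
    """z-scores with the population standard deviation (divisor N)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise InputError("normalization requires at least 2 values")
    mean = values.mean()
    sd = values.std()  # ddof=0
    if sd < 1e-12 * abs(mean) + 1e-300:
        raise DegenerateProfileError(
            "profile is constant (sd ~ 0); z-normalization undefined"
        )
    return (values - mean) / sd


def normalize(profile: StructuralProfile) -> StructuralProfile:
    """z-normalize a profile to mean 0, standard deviation 1 (population)."""
    return StructuralProfile(
        keys=list(profile.keys),
        values=znorm(profile.values),
        kind=NORMALIZED,
        context=profile.context,
    )


def sliding_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks at both chain ends."""
    if window < 1 or window % 2 == 0:
        raise InputError(f"window must be an odd positive integer, got {window}")
    values = np.asarray(values, dtype=float)
    if window > len(values):
        raise InputError(
            f"window {window} exceeds profile length {len(values)}"
        )
    if window == 1:
        return values.copy()
    return (
        pd.Series(values)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def smooth(profile: StructuralProfile, window: int = 5) -> StructuralProfile:
    """Sliding-window smoothing (centered mean, truncated at the ends)."""
    return StructuralProfile(
        keys=list(profile.keys),
        values=sliding_mean(profile.values, window),
        kind=profile.kind,
        context=profile.context,
    )
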