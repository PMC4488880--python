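"""Agreement between structural and conservation profiles.

Three levels of analysis:

* per-subunit Pearson correlation between the normalized conservation
  profile and a normalized structural profile (WCN z or c-distance z);
* the binned-trend analysis: conservation z-scores are binned (default
  width 0.3 z-units, half-open bins anchored at 0), the structural z is
  averaged per bin, and an ordinary least-squares line is fitted through
  the (bin center, bin mean) points — its r² measures how linear the
  structure–conservation relationship is;
* batch summaries that run the whole pipeline over many structures and
  average the correlations per model kind.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import conservation as cons_mod
from . import profiles as prof_mod
from . import structure_io
from .conservation import ConservationProfile, SiteMap
from .errors import (
    BatchError,
    CapsidProfError,
    DegenerateProfileError,
    InputError,
    InsufficientOverlapError,
)
from .profiles import NORMALIZED, StructuralProfile
from .structure_io import ResidueKey

logger = logging.getLogger(__name__)


@dataclass
class ProfilePair:
    """Conservation (x) and structural (y) z-scores on a common residue set."""

    keys: list[ResidueKey]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.keys) == len(self.x) == len(self.y)):
            raise InputError("pair fields differ in length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise InputError("non-finite values in profile pair")

    @property
    def n(self) -> int:
        return len(self.x)


def pair_profiles(cons: ConservationProfile, struct: StructuralProfile,
                  sitemap: SiteMap) -> ProfilePair:
    """Join the two normalized profiles on the residues mapped by *sitemap*.

    Output order follows the structural profile (structure order).
    """
    if not cons.normalized:
        raise InputError("conservation profile must be normalized before pairing")
    if struct.kind != NORMALIZED:
        raise InputError("structural profile must be normalized before pairing")
    score_by_site = dict(zip(cons.positions.tolist(), cons.scores))
    keys, xs, ys = [], [], []
    for key, y in zip(struct.keys, struct.values):
        site = sitemap.site_of(key)
        if site is None or site not in score_by_site:
            continue
        keys.append(key)
        xs.append(score_by_site[site])
        ys.append(y)
    if len(keys) < 3:
        raise InsufficientOverlapError(
            f"only {len(keys)} residues shared between the profiles; "
            "need at least 3"
        )
    return ProfilePair(keys, np.array(xs), np.array(ys))


def pearson(pair: ProfilePair) -> float:
    """Product-moment correlation between the paired z-scores."""
    if pair.n < 3:
        raise InsufficientOverlapError("Pearson correlation requires n >= 3")
    if np.ptp(pair.x) == 0 or np.ptp(pair.y) == 0:
        raise DegenerateProfileError("constant profile: correlation undefined")
    return float(stats.pearsonr(pair.x, pair.y).statistic)


# ---------------------------------------------------------------------------
# binned trend

@dataclass
class TrendFit:
    slope: float
    intercept: float
    r2: float


@dataclass
class BinnedTrend:
    """Per-conservation-bin means of the structural z, with a linear fit."""

    bin_width: float
    bin_edges: np.ndarray     # left edges k·w of the occupied bins
    bin_x_means: np.ndarray   # within-bin mean of the conservation z
    bin_means: np.ndarray     # within-bin mean of the structural z
    bin_counts: np.ndarray
    fit: TrendFit | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_edges + self.bin_width / 2


def binned_trend(pair: ProfilePair, bin_width: float = 0.3,
                 min_count: int = 1) -> BinnedTrend:
    """Bin conservation z into half-open intervals [k·w, (k+1)·w), k ∈ ℤ,
    average both z-scores per occupied bin, and fit an OLS line through the
    (bin mean x, bin mean y) points, bins weighted equally.

    The abscissa of the fit is the within-bin mean of x rather than the
    geometric bin center: partially filled edge bins then sit at their true
    mean, so exactly linear data yield r² = 1 to machine precision.

    With fewer than 2 occupied bins the trend is returned without a fit.
    """
    if pair.n < 3:
        raise InsufficientOverlapError("binned trend requires n >= 3")
    if bin_width <= 0:
        raise InputError("bin width must be positive")
    k = np.floor(pair.x / bin_width).astype(int)
    ks = np.unique(k)
    edges, x_means, means, counts = [], [], [], []
    for kk in ks:
        mask = k == kk
        if mask.sum() < min_count:
            continue
        edges.append(kk * bin_width)
        x_means.append(pair.x[mask].mean())
        means.append(pair.y[mask].mean())
        counts.append(int(mask.sum()))
    trend = BinnedTrend(
        bin_width=bin_width,
        bin_edges=np.array(edges),
        bin_x_means=np.array(x_means),
        bin_means=np.array(means),
        bin_counts=np.array(counts, dtype=int),
    )
    if len(edges) >= 2:
        res = stats.linregress(trend.bin_x_means, trend.bin_means)
        trend.fit = TrendFit(slope=float(res.slope),
                             intercept=float(res.intercept),
                             r2=float(res.rvalue ** 2))
    return trend


# ---------------------------------------------------------------------------
# end-to-end pipeline and batch summaries

@dataclass(frozen=True)
class CompareJob:
    """One structure/conservation comparison task."""

    structure: str
    assembly: str            # "asu" or an assembly id
    subunit: str
    conservation: str        # grades file path
    model_kind: str          # "wcn" or "cdist"
    offset: int = 0
    smooth_window: int = 5
    force: bool = False
    label: str = ""

    @property
    def job_id(self) -> str:
        return self.label or f"{self.structure}:{self.subunit}:{self.model_kind}"


def compare_structure(job: CompareJob) -> tuple[ProfilePair, float]:
    """Run the full per-structure pipeline and return the pair and its r.

    Pipeline: read (+ assembly expansion) → structural profile in
    whole-capsid context → normalize → parse conservation → smooth →
    normalize → map by residue number → pair → Pearson r.
    """
    model = structure_io.read_structure(job.structure, assembly=job.assembly)
    if job.model_kind == "wcn":
        sp = prof_mod.wcn_profile(model, job.subunit)
    elif job.model_kind == "cdist":
        sp = prof_mod.cdistance_profile(model, job.subunit)
    else:
        raise InputError(f"unknown model kind {job.model_kind!r}")
    sp = prof_mod.normalize(sp)
    cons = cons_mod.parse_rate4site(job.conservation)
    if job.smooth_window > 1:
        cons = cons_mod.smooth_conservation(cons, job.smooth_window)
    cons = cons_mod.normalize_conservation(cons)
    sitemap = cons_mod.map_to_structure(
        cons, model, job.subunit, offset=job.offset, force=job.force
    )
    pair = pair_profiles(cons, sp, sitemap)
    return pair, pearson(pair)


@dataclass
class BatchSummary:
    """Per-structure correlations and their per-model-kind averages."""

    per_structure: list[tuple[str, str, float, int]]  # (id, kind, r, n)
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def averages(self) -> dict[str, float]:
        by_kind: dict[str, list[float]] = {}
        for _, kind, r, _ in self.per_structure:
            by_kind.setdefault(kind, []).append(r)
        return {kind: float(np.mean(rs)) for kind, rs in sorted(by_kind.items())}


def batch_compare(jobs: list[CompareJob]) -> BatchSummary:
    """Run many comparison jobs; per-job failures are recorded, not fatal."""
    if not jobs:
        raise InputError("empty job list")
    rows: list[tuple[str, str, float, int]] = []
    failures: list[tuple[str, str]] = []
    for job in jobs:
        try:
            pair, r = compare_structure(job)
            rows.append((job.job_id, job.model_kind, r, pair.n))
        except CapsidProfError as exc:
            logger.warning("job %s failed: %s", job.job_id, exc)
            failures.append((job.job_id, str(exc)))
    if not rows:
        raise BatchError(
            f"all {len(jobs)} jobs failed; first error: {failures[0][1]}"
        )
    return BatchSummary(rows, failures)


def pooled_pair(pairs: list[ProfilePair]) -> ProfilePair:
    """Concatenate normalized pairs from several structures for a pooled
    binned-trend analysis."""
    if not pairs:
        raise InputError("no pairs to pool")
    return ProfilePair(
        keys=[k for p in pairs for k in p.keys],
        x=np.concatenate([p.x for p in pairs]),
        y=np.concatenate([p.y for p in pairs]),
    )
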