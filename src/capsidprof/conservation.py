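"""Sequence conservation profiles: ingestion, a stand-in scorer, mapping.

Conservation here means a site-specific substitution rate, with the
orientation fixed throughout the package: **a lower score means a more
conserved site**.  Scores are never sign-flipped anywhere; under this
convention a loosely packed, surface-exposed residue (large WCN z, large
c-distance z) is expected to carry a *larger* conservation score.

The primary source of scores is a Rate4Site/ConSurf grades file (the rates
are inferred by those external tools from a homolog alignment and a
phylogeny; this package only ingests them).  For self-contained pipelines
an MSA-based Shannon-entropy scorer is provided; it is a deliberately
simple stand-in, not a substitute for phylogeny-aware rate inference, but
it has the same orientation (higher entropy = less conserved).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

from .errors import InputError, MappingError
from .profiles import sliding_mean, znorm
from .structure_io import CalphaModel, ResidueKey

_GAPS = {"-", ".", "*"}


@dataclass
class ConservationProfile:
    """Per-site substitution-rate scores along one protein sequence."""

    positions: np.ndarray    # 1-based site indices, strictly increasing
    aas: list[str]           # query residue letters ("?" if unknown)
    scores: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if not (len(self.positions) == len(self.aas) == len(self.scores)):
            raise InputError("conservation fields differ in length")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise InputError("site positions must be strictly increasing")
        if not np.all(np.isfinite(self.scores)):
            raise InputError("non-finite conservation scores")

    def __len__(self) -> int:
        return len(self.positions)


# ---------------------------------------------------------------------------
# Rate4Site / ConSurf grades files

def parse_rate4site(path: str | os.PathLike, score_column: int | None = None
                    ) -> ConservationProfile:
    """Parse a Rate4Site/ConSurf grades file or a plain site/score table.

    Accepted dialects, sniffed from the first data row:

    * classic grades layout: ``POS  SEQ  SCORE  [QQ-INTERVAL  STD  MSA...]``
    * minimal 2-column TSV: ``pos  score``
    * 3-column TSV: ``pos  aa  score``

    Comment lines (``#``) and blank lines are skipped.  Scores are taken
    unmodified from the rate column (``score_column`` overrides the sniffed
    0-based column index).
    """
    positions, aas, scores = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            try:
                pos = int(toks[0])
            except ValueError as exc:
                raise InputError(
                    f"{path}:{lineno}: expected an integer site index, "
                    f"got {toks[0]!r}"
                ) from exc
            has_aa = len(toks) >= 2 and len(toks[1]) == 1 and toks[1].isalpha()
            col = score_column if score_column is not None else (2 if has_aa else 1)
            try:
                score = float(toks[col])
            except (IndexError, ValueError) as exc:
                raise InputError(
                    f"{path}:{lineno}: cannot read score from column {col}"
                ) from exc
            positions.append(pos)
            aas.append(toks[1].upper() if has_aa else "?")
            scores.append(score)
    if not positions:
        raise InputError(f"no data rows in {path}")
    return ConservationProfile(np.array(positions), aas, np.array(scores))


def write_grades(cons: ConservationProfile, path: str | os.PathLike,
                 header: str = "") -> None:
    """Write a grades-style table readable by :func:`parse_rate4site`."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# POS SEQ SCORE\n")
        for pos, aa, score in zip(cons.positions, cons.aas, cons.scores):
            fh.write(f"{pos} {aa if aa != '?' else 'X'} {score:.10g}\n")


# ---------------------------------------------------------------------------
# stand-in scorer

def entropy_conservation(msa_path: str | os.PathLike, query: str
                         ) -> ConservationProfile:
    """Per-site Shannon entropy (bits) of an aligned FASTA, as conservation.

    For each alignment column where the query has a residue, the score is
    the entropy of the amino-acid frequencies in that column with gaps
    excluded from the counts.  Positions index the ungapped query sequence
    (1-based).  Higher entropy = more variable = less conserved, matching
    the package-wide orientation.

    This is a documented stand-in for phylogeny-aware rate inference
    (Rate4Site): it ignores tree topology and sequence redundancy.
    """
    try:
        aln = AlignIO.read(os.fspath(msa_path), "fasta")
    except ValueError as exc:
        raise InputError(f"cannot read alignment {msa_path}: {exc}") from exc
    ids = [rec.id for rec in aln]
    if query not in ids:
        raise InputError(f"query {query!r} not in alignment (ids: {ids[:5]}...)")
    qseq = str(aln[ids.index(query)].seq)

    positions, aas, scores = [], [], []
    site = 0
    for col in range(aln.get_alignment_length()):
        q = qseq[col].upper()
        if q in _GAPS:
            continue
        site += 1
        counts: dict[str, int] = {}
        for rec in aln:
            c = str(rec.seq[col]).upper()
            if c in _GAPS:
                continue
            counts[c] = counts.get(c, 0) + 1
        total = sum(counts.values())
        ent = -sum((k / total) * math.log2(k / total) for k in counts.values())
        positions.append(site)
        aas.append(q)
        scores.append(ent)
    return ConservationProfile(np.array(positions), aas, np.array(scores))


# ---------------------------------------------------------------------------
# mapping onto structure

@dataclass
class SiteMap:
    """One-to-one pairing of conservation sites with structure residues."""

    pairs: list[tuple[ResidueKey, int]]
    unmapped_structure: list[ResidueKey] = field(default_factory=list)
    unmapped_sites: list[int] = field(default_factory=list)
    mismatches: list[tuple[ResidueKey, int]] = field(default_factory=list)

    def site_of(self, key: ResidueKey) -> int | None:
        try:
            return self._by_key.get(key)
        except AttributeError:
            self._by_key = {k: s for k, s in self.pairs}
            return self._by_key.get(key)


def map_to_structure(
    cons: ConservationProfile,
    model: CalphaModel,
    subunit: str,
    offset: int = 0,
    max_mismatch_frac: float = 0.05,
    force: bool = False,
) -> SiteMap:
    """Map site *p* to the subunit residue numbered ``p + offset``.

    Mapping is by author residue number (blank insertion code);
    insertion-coded residues are left unmapped.  Where both amino-acid
    letters are known, disagreements are recorded; if their fraction
    exceeds *max_mismatch_frac* the mapping fails unless *force*.
    """
    rows = model.subunit_indices(subunit)
    by_num: dict[int, ResidueKey] = {}
    unmapped_structure: list[ResidueKey] = []
    for i in rows:
        key = model.residues[i]
        if key.icode:
            unmapped_structure.append(key)
        else:
            by_num[key.seq_num] = key

    pairs: list[tuple[ResidueKey, int]] = []
    unmapped_sites: list[int] = []
    mismatches: list[tuple[ResidueKey, int]] = []
    mapped_nums = set()
    for pos, aa in zip(cons.positions, cons.aas):
        key = by_num.get(int(pos) + offset)
        if key is None:
            unmapped_sites.append(int(pos))
            continue
        mapped_nums.add(key.seq_num)
        pairs.append((key, int(pos)))
        if aa not in ("?", "X") and key.aa != "X" and aa != key.aa:
            mismatches.append((key, int(pos)))
    unmapped_structure.extend(
        by_num[n] for n in sorted(set(by_num) - mapped_nums)
    )
    if not pairs:
        raise InputError(
            f"no conservation sites map onto subunit {subunit!r} "
            f"with offset {offset}"
        )
    frac = len(mismatches) / len(pairs)
    if frac > max_mismatch_frac and not force:
        preview = ", ".join(
            f"site {p} ({model.residues[model.index_of(k)].aa} vs structure)"
            for k, p in mismatches[:10]
        )
        raise MappingError(
            f"{len(mismatches)}/{len(pairs)} mapped sites disagree in amino "
            f"acid ({frac:.1%} > {max_mismatch_frac:.1%}); check the offset "
            f"or pass force. First mismatches: {preview}"
        )
    return SiteMap(pairs, unmapped_structure, unmapped_sites, mismatches)


# ---------------------------------------------------------------------------
# normalization / smoothing (same contracts as structural profiles)

def normalize_conservation(cons: ConservationProfile) -> ConservationProfile:
    """z-normalize scores (population sd), preserving site order."""
    return ConservationProfile(
        positions=cons.positions.copy(),
        aas=list(cons.aas),
        scores=znorm(cons.scores),
        normalized=True,
    )


def smooth_conservation(cons: ConservationProfile, window: int = 5
                        ) -> ConservationProfile:
    """Centered sliding-window mean of the scores (noise reduction)."""
    return ConservationProfile(
        positions=cons.positions.copy(),
        aas=list(cons.aas),
        scores=sliding_mean(cons.scores, window),
        normalized=cons.normalized,
    )
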