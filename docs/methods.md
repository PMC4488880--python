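# Methods

## Models

**Packing density / WCN.** The packing density of residue *i* is the
cutoff-free inverse-square contact sum `n_i = Σ_{j≠i} 1/r_ij²` over the Cα
atoms of *all* residues in the model; the profile value is its reciprocal,
the weighted contact number `w_i = 1/n_i` (units Å²·residue⁻¹ up to the
reciprocal; treated as dimensionless after normalization). The sum is
evaluated exactly — vectorized in memory-bounded blocks, never with a
cutoff, neighbor list, or any other truncation — because the model is
defined without a cutoff radius and the far-field contributions of a large
shell are not negligible in aggregate. For a subunit of a capsid the sum
still runs over the whole assembly: a residue at a subunit–subunit
interface is tightly packed only in whole-capsid context.

**Centroid distance.** The Euclidean distance from each Cα to the
unweighted mean of all Cα positions of the model, in Å. The centroid is of
the whole capsid, never the single subunit. This is an isotropic model: it
carries no orientation information and is only expected to work for
near-spherical assemblies; for non-spherical proteins the packing-density
model is the appropriate one.

**Normalization.** Profiles are z-normalized, `z = (x − mean)/sd`, with the
*population* standard deviation (divisor N). Sample vs population is an
arbitrary convention here — the two differ by a constant factor, which
leaves every Pearson correlation unchanged — but one must be fixed and
tested; population sd makes `mean(z²) = 1` exactly. A profile is rejected
as degenerate when `sd < 1e-12·|mean| + 1e-300`; the canonical degenerate
input is the radius profile of a mathematically perfect sphere. z-scores
are unbounded and are deliberately never clamped to any interval.

**Conservation orientation.** A conservation score is a site-specific
substitution rate: lower = more conserved. This orientation is fixed at
ingestion and never flipped anywhere in the package — under it, both
structural z-profiles are expected to correlate *positively* with
conservation scores (exposed, loosely packed residues evolve faster). A
silent sign flip is the most dangerous bug this pipeline could have, so the
tests pin the orientation end to end.

**Smoothing.** The conservation profile may be smoothed before
normalization with a centered sliding-window mean; the window shrinks at
the chain ends (a length-5 window uses 3 points at the first residue).
Default window 5 — small enough to preserve loop-scale features, large
enough to suppress single-site scatter; configurable, odd, and window 1 is
the identity. Smoothing is applied to the conservation profile only;
structural profiles can be smoothed explicitly for visual comparison but
are not by default.

**Correlation and binned trend.** Agreement is the Pearson product-moment
correlation over residues present in both profiles (minimum 3). The
binned-trend analysis bins conservation z into half-open intervals
`[k·w, (k+1)·w)`, `k ∈ ℤ`, anchored at 0 with default width w = 0.3
z-units, averages the structural z per occupied bin, and fits an
equal-weight OLS line through the per-bin means. The fit abscissa is the
*within-bin mean* of the conservation z rather than the geometric bin
center: edge bins are usually only partly filled, and placing them at their
true mean removes the resulting bias — with the practical consequence that
exactly linear data give r² = 1 to machine precision. Both abscissae are
reported in the trend table. Bins below a configurable minimum occupancy
(default 1) are dropped from the fit; with fewer than two occupied bins the
trend is returned without a fit.

## Structure handling

Structures are reduced to one Cα per residue. Parsing (PDB and mmCIF) is
delegated to gemmi. Policies where the field's conventions vary:

* **Assemblies.** Biological-assembly operators stored in the file
  (REMARK 350 / mmCIF assembly generators) are honored on request
  (`--assembly 1`); an external plain-text operator file (rows of 12
  numbers: row-major rotation + translation) is also accepted because many
  capsid depositions ship pre-expanded or with nonstandard operator
  records. Expansion order is transform-major, chain-minor, and subunit
  identifiers are `<chain><transform-index>` (`A0`, `A1`, …). Rotations
  are validated (orthonormal to 1e-6, det +1). No symmetry inference is
  performed: operators must be supplied or stored.
* **Altlocs.** Highest occupancy wins; ties go to the first listed.
* **Nonstandard residues.** Amino acids with a Cα (e.g. selenomethionine)
  are kept and mapped to the parent one-letter code via gemmi's tabulated
  residues, else to X. Waters and non-amino-acid ligands are excluded.
* **Missing Cα.** The residue is skipped with a logged warning.
* **Numbering.** Author chain ids and residue numbers are the user-facing
  keys, matching conservation-file conventions; coordinates are Å
  throughout.
* **Coincident atoms.** A Cα pair closer than 1e-6 Å makes the contact sum
  singular and raises a hard error naming both residues — safer than
  silent exclusion.

Site-to-residue mapping is by author residue number plus a user offset
(site p ↔ seq_num p + offset), not by sequence alignment — transparent and
adequate for single-chain viral proteins. Amino-acid letters are
cross-checked where known; if more than 5% of mapped sites disagree the
mapping fails (listing the first mismatches) unless forced.
Insertion-coded residues are left unmapped, since grades files carry no
insertion codes.

The colored-structure writer emits a Cα-only PDB with the profile value in
the fixed-width `%6.2f` B-factor column (values outside [−99.99, 999.99]
are clamped with a log message; round-trip precision is therefore the
field's 0.01 quantization) or a per-residue TSV attribute table for
viewer-side coloring.

## Rate4Site/ConSurf ingestion and the entropy stand-in

The grades parser sniffs, per first data row, the classic Rate4Site layout
(`POS SEQ SCORE …`, extra columns ignored) and minimal 2/3-column tables;
comment and blank lines are skipped; positions must be strictly
increasing. The continuous rate column is the default score (a column
override exists because server output layouts vary). Scores are taken
unmodified.

The built-in scorer — per-column Shannon entropy (bits) of an aligned
FASTA, gaps excluded from counts, positions indexed on the ungapped query —
is a deliberately simple stand-in so the full pipeline can run without
external servers. It ignores phylogeny and sequence redundancy and is
documented as such; it shares the rate orientation (higher = less
conserved).

## Synthetic data: what it emulates and what it does not

`make_shell_capsid` emulates the gross geometry of an icosahedral shell:
N subunits × M residues placed quasi-uniformly (deterministic Fibonacci
golden-angle spiral) on one or more concentric spherical shells, with
Gaussian radial jitter, partitioned shell-major into contiguous chains so
that sequence neighbors are also spatial neighbors, as along a real
backbone. A 1 Å minimum Cα separation is enforced by re-drawing the jitter
of violators (bounded retries), keeping the inverse-square sum
well-conditioned. Defaults are sized to the study conditions used
throughout the tests: 60 subunits × 100 residues (6000 Cα), shell radius
100 Å (layered variant 80/90/100 Å), radial jitter 1.5 Å — dimensions and
coordinate noise typical of small icosahedral capsid crystal structures.

Synthetic conservation is `score_i = slope·z_i + ε_i`, `ε ~ N(0, σ²)`,
generated on the *normalized* structural profile so the population
correlation has the closed form ρ = slope/√(slope² + σ²); σ is chosen by
inverting this (σ = 1.0202 gives ρ = 0.70 at unit slope). Parameter
recovery is asserted as the mean estimated r over 20 seeds within ±0.05 of
ρ ∈ {0.5, 0.7, 0.9}; the centroid-model recovery runs on the three-shell
variant, whose radius profile has real between-layer variance. Recovery
runs disable conservation smoothing (window 1): the ground-truth link is
defined on unsmoothed profiles, and smoothing would change the estimand
(it preferentially averages away the iid noise of spatial neighbors),
not test the estimator.

What the generator does **not** emulate: real protein folds, icosahedral
T-number lattices, inter-subunit interfaces with specific contacts,
sequence evolution under substitution models, alignment uncertainty, or
the error structure of Rate4Site scores. Passing tests therefore
demonstrate that the pipeline's arithmetic, plumbing and conventions are
correct and self-consistent under known ground truth — not that the
structural models achieve any particular accuracy on real capsids, which
depends on downloaded structures and database-derived conservation scores
outside this package's scope.

## Numerical choices

* WCN is computed with exact blocked summation (`scipy` squared-distance
  kernels, default 2048-row blocks; block size provably does not affect
  results and is tested not to).
* Population-sd z-scores; degeneracy threshold as above.
* Bin anchoring at z = 0 with half-open `[k·w, (k+1)·w)` intervals makes
  binning reproducible and independent of the data range.
* Trend fits use `scipy.stats.linregress` on bin means, equal weights.
* The Fibonacci spiral is fully deterministic; all stochastic elements
  (jitter, conservation noise) take explicit integer seeds, and CLI runs
  with identical inputs and seeds are byte-identical.
* Problem sizes in the test-suite and acceptance runs (60×100 synthetic
  capsids, 20 seeds per condition, ≤500-residue oracle comparisons) were
  chosen as the smallest scales at which the statistical assertions are
  stable.

## Known limitations

* Cα-only; no all-atom or side-chain-weighted WCN variants, and no
  B-factor/flexibility analysis.
* Mapping is numbering-based; proteins whose grades files use a different
  numbering frame need the `--offset` flag (no alignment-based rescue).
* The centroid model is expected to degrade on non-spherical assemblies by
  construction; the package computes it regardless.
* Heteromeric capsids are handled per-subunit; correlations for a
  heteromer can be computed per viral protein and averaged via the batch
  interface, or on concatenated subunits by pooling pairs — both are
  exposed, neither is declared canonical.
* `--operators` expansion composes with, but does not read, mmCIF
  `pdbx_struct_oper_list` expressions such as operator products; files
  using those must rely on their stored assembly generators.
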