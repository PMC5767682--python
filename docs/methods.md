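# Methods

This note documents the models, conventions and numerical choices behind
`condock`, in the order the protocol runs.

## Symmetry-corrected RMSD

Two docked poses of the same molecule are compared by the RMSD minimised over
atom correspondences: per element class, the squared-distance cost matrix is
solved with the Hungarian algorithm (`scipy.optimize.linear_sum_assignment`);
solving block-diagonally per element is exactly equivalent to a single matrix
with infinite cross-element costs, and cheaper. Key conventions:

- **Heavy atoms only** by default. Docking engines differ in hydrogen
  handling, and hydrogen placement carries no information about the binding
  position; a flag restores all-atom mode.
- **No superposition.** The 2.0 Å agreement criterion compares *binding
  placements* in the fixed receptor frame, not conformers; superposing first
  would let a pose on the far side of the receptor "match" a consensus pose.
  Consequently the metric is translation-invariant only under a *common*
  translation of both poses (a frame change), which is the invariant that
  matters.
- **Ties** between equal-cost assignments are irrelevant to the value; any
  minimising assignment is accepted.
- **Cross-ligand (relaxed) mode** for clustering chemically similar but
  non-identical compounds: a rectangular assignment matches every atom of the
  smaller molecule to distinct atoms of the larger, ignoring elements, and
  the RMSD is normalised by the matched-atom count. This is a pragmatic
  dissimilarity between placements of related scaffolds, not a chemically
  meaningful alignment; it is used only where the compounds in a series
  differ in size.

Correctness is anchored by an exhaustive-permutation oracle: for poses of
≤ 7 heavy atoms the assignment solution is compared against the brute-force
minimum over all element-respecting permutations (tolerance 1e-8 Å).

## Consensus matching and region derivation

All cross-engine pairs with Hungarian RMSD ≤ 2.0 Å (configurable) form the
consensus subset. The refined search region is derived from the unweighted
mean of every heavy atom of every pose appearing in the subset: sphere radius
= maximum atom distance from that centroid (+ optional pad); box edges =
doubled per-axis maximum deviation (+ 2·pad). Both dialects therefore contain
every consensus atom by construction. Zero-extent axes (single-atom or
single-pose input) are floored at 1 Å with a warning, because docking engines
reject zero volumes.

The initial seed region defaults to an 18 Å-radius sphere and a 32 Å cube
centred on the anchor residue's γ-carbon (CG2 for threonine; the atom name is
configurable). Residue numbering is taken verbatim from the input file; a
per-chain offset (default 0) accommodates numbering schemes anchored at a
signal-peptide cleavage site.

## Flexible-residue selection

Candidates are residues with at least one side-chain heavy atom inside the
sphere dialect (glycine falls back to Cα). Selection fills `n = 10` slots in
tiers: (1) all residues from the supplied mutated list, (2) polar residues
(SER, THR, TYR, CYS, ASN, GLN, HIS, LYS, ARG, ASP, GLU — configurable),
(3) everything else. Within tiers 2–3 the "even distribution" aim is
operationalised as greedy farthest-point sampling on side-chain centroids,
seeded by the residues already selected in higher tiers; with an empty seed
the first pick is the lowest (chain, residue-number) key, which also breaks
all ties. Greedy max–min dispersion is deterministic and near-optimal; it is
not guaranteed to attain the exhaustive max–min optimum for every subset
size, so the oracle test pins a configuration where the two provably
coincide.

## Borda aggregation

Each metric ranks the matched pairs after orientation normalisation
(Vina score lower-better; GoldScore and ChemPLP higher-better — each engine's
documented convention, configurable). Ties receive fractional (mean) ranks so
the result cannot depend on input order. Points per item are Σ_m (n − rank_m)
— the standard Borda convention in which a unanimous winner earns (n−1)·m —
and the final order sorts points descending, breaking ties by the first
lower-better metric's value and then input order. Pair-level metrics are read
from their native engine's pose: the Vina score from the engine-B member,
GoldScore/ChemPLP from the engine-A member. Items missing any requested
metric are excluded from the whole run (with a warning) rather than
per-metric, so `n` is a single number and points remain commensurable across
metrics.

## Redundancy removal and clustering

De-duplication walks the pairs in final Borda order and keeps a pair only if
its engine-A pose lies more than 2.0 Å (Hungarian RMSD) from every kept
engine-A pose, stopping at 20 pairs. Using the same 2.0 Å scale as matching
gives the protocol one coherent distance everywhere.

The top five pairs per compound are pooled across the chemical series and
clustered agglomeratively (`scipy.cluster.hierarchy`, complete linkage by
default) on the pairwise Hungarian-RMSD matrix of the engine-A poses, cutting
the tree at 2.0 Å. Linkage and cutoff are exposed as parameters and are the
package's own defaults, not literature facts. Cluster representatives are the
members with the best final Borda rank, ties resolved by lowest mean RMSD to
the rest of the cluster. Consensus modes are clusters with population ≥ 2,
ordered by population then mean Borda rank; a mode's value as a binding-site
call rests on spanning several compounds of the series.

## Interaction geometry

Reported "distance to residue X" figures use the minimum heavy-atom distance
between the ligand selection and the residue side chain by default, with a
centroid mode available, because published "∼X Å" figures rarely state their
convention — reports print both. Hydrogen bonds use standard geometric
criteria: donor–acceptor (N/O) heavy-atom distance ≤ 3.5 Å and, when the
structure contains explicit hydrogens, D–H···A angle ≥ 120° with the
hydrogen assigned to its donor by a 1.3 Å covalent cutoff. In a structure
with explicit hydrogens, polar atoms lacking one are treated as
acceptors-only; a hydrogen-free structure falls back to distance-only
screening and the report is flagged accordingly. Pocket residues are those
with any side-chain heavy atom within 4.5 Å of the ligand; the chain
contributing the most contact atoms is labelled the principal (+) subunit,
the rest complementary (−), overridable in configuration.

## Density simulation and fit scores

Simulated maps are sums of spherical Gaussians at atom centres with amplitude
proportional to atomic number. The width convention treats the nominal
resolution as the Gaussian FWHM, σ = resolution / (2·√(2·ln 2)); a
resolution/π alternative is selectable because published segment scores
depend on the generating tool's convention, and reproducing a specific
printed value may require matching it. Grids are padded 4σ beyond the
bounding box; when scoring against an experimental map, the simulation is
evaluated directly on that map's grid. Congruence (shape, voxel, origin) is
enforced; an explicit trilinear `regrid` helper is provided rather than
implicit resampling, so scores are bit-stable.

- **CCC**: Pearson correlation of voxel values, optionally over a boolean
  mask. Zero-variance inputs are an error, not a 0.
- **Segment CCC**: the CCC restricted to voxels within 3 Å (default) of the
  segment's atoms. A model scored against its own simulated map gives
  ≥ 0.99 by construction; with 3.8 Å inter-residue spacing and broad (≈6 Å)
  Gaussians, density from residues flanking the segment leaks into the mask,
  which bounds how low a displaced-segment score can go — the planted
  register-error fixtures therefore use a sharper simulated resolution and a
  2 Å mask.
- **Manders overlap**: Σab / √(Σa²·Σb²) after thresholding at zero, in
  [0, 1]; 1 for identical maps, 0 for disjoint supports.
- **Loop ranking** orders candidate models by segment CCC, stable under ties.

## Register shift and percent identity

The register-shift correction inserts a run of gap columns in the first
sequence immediately after a labelled residue (one-letter code + ungapped
ordinal, e.g. `P236`); the partner sequence keeps its columns and gains
trailing gaps so the alignment stays rectangular, and named column regions
are remapped (regions ending at the insertion point are unchanged; regions
beyond it shift). Removing the inserted columns restores the original
alignment exactly.

Percent identity over a named region counts identical columns over *aligned*
columns: a column with a residue in at least one sequence is aligned (so
gap-versus-residue counts against identity), and double-gap columns are
excluded from the denominator. The raw value is returned; reports round to
the nearest integer.

## Synthetic fixtures

The generator emulates the structure of a two-engine docking campaign, not
its energetics:

- **Pose ensembles**: 50 + 20 poses per engine by default (the two engines'
  characteristic solution counts), placed at planted mode centres ≥ 12 Å
  apart with per-atom Gaussian noise (default σ = 0.3 Å, giving intra-mode
  pair RMSDs ≈ 0.7 Å, comfortably inside the 2.0 Å criterion) and optional
  within-element atom permutation. Decoys are rejection-sampled ≥ 8 Å from
  every mode centre so threshold tests are unambiguous.
- **Score tables**: three metrics (one lower-better, two higher-better)
  linear in a planted quality permutation, so the noiseless Borda aggregate
  reproduces that permutation exactly; Gaussian score noise degrades it
  smoothly.
- **Toy receptors**: a ring of residues around a pocket with a
  γ-carbon-bearing anchor threonine and tagged "mutated" residues, enough to
  exercise region seeding, tier selection and contact geometry.
- **Planted densities**: simulated maps with one segment's density displaced,
  for loop-ranking ground truth.

All generators are bit-deterministic given their seed. What passing these
fixtures does **not** show: real engines produce correlated, non-Gaussian
pose scatter, scores with heavy tails and systematic biases, and ligands with
rotatable bonds whose conformers differ between engines — recovery rates on
real campaigns will be lower than the clean planted-mode recovery here. The
fixtures establish that the machinery is correct, not that the protocol's
biological conclusions transfer.

## Problem sizes and determinism

Tests and the acceptance script run the protocol at the protocol's own scale
(50 + 20 poses per engine, three compounds per series, 200 oracle pose pairs,
100 Borda tables) with small rigid ligands; density fixtures use ~12-residue
Cα traces on coarse grids. One integer seed drives every random stream via
`numpy.random.default_rng`.

## Known limitations

- Cross-ligand relaxed RMSD ignores chemistry entirely; for series with very
  different sizes a maximum-common-substructure metric would be better (out
  of scope here).
- Hydrogen-bond detection has no donor/acceptor chemistry beyond N/O and
  explicit hydrogens — no charged-group special-casing, no π interactions.
- The principal-subunit (+/−) call is a contact-count heuristic.
- MOL2 parsing relies on RDKit's SYBYL handling; exotic atom types may need
  pre-conversion.
- Reproducing a specific published segment-CCC value additionally requires
  the original tool's Gaussian-width and mask conventions; both knobs are
  exposed but defaults are this package's own.
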