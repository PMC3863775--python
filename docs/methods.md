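# Methods

This note documents the models, conventions, defaults and limitations of
capsidkit, in the order the analyses build on one another.

## Structures, selections, superposition

The in-memory hierarchy (Structure → Chain → Residue → AtomRecord) keeps
*authored* residue numbers, and all residue ranges everywhere in the
toolkit are inclusive and 1-based in that numbering — the convention in
which capsid literature reports selections such as "residues 5–331".
Missing residues inside a requested range are skipped and listed in a gap
report rather than raising; an entirely empty selection is an explicit
error. Alternate locations collapse to the highest-occupancy conformer
with a deterministic altloc-label tie-break. "Backbone" means N, Cα, C,
O; "trace" means Cα only; ensemble RMSD comparisons default to backbone
atoms restricted to residues resolved (with all four atoms) in *every*
conformer, which is how partially disordered quasi-equivalent copies are
compared in practice.

Superposition is closed-form least squares (SVD of the covariance with a
determinant correction restricting the optimum to proper rotations), and
is unweighted. Reflections are never returned; the constrained optimum for
mirror-related point sets is validated in the tests against an
independent brute-force quaternion search.

PDB and mmCIF parsing/serialisation delegate to gemmi; FASTA to
Biopython. PDB output is refused beyond the format's fixed-column
capacity (62 chains / 99 999 atoms) with an instruction to use mmCIF —
relevant because an expanded T = 7 capsid has 840 chains.

## Fold topology

An element partition is an ordered set of labeled, non-overlapping,
internally contiguous residue ranges on one chain; elements shorter than
3 residues are rejected because their junction anchors would be
degenerate. Junction anchors are the Cα atoms of the first/last
*resolved* residue of each element (the standard trace atom; nothing
finer is warranted by map-derived models). For a candidate order, the
junction Eᵢ→Eⱼ is measured in the native structure as the distance from
Eᵢ's C-anchor to Eⱼ's N-anchor — the gap a linker would have to span if
the elements were rewired without refolding. The feasibility cutoff
d_max defaults to 20 Å: bridgeable by a ≤ 6-residue extended linker at
~3.5 Å per residue. The default is a design choice documented here, not a
measured constant; the only geometric fact the analysis depends on is
that ~42 Å is far beyond it. Chain-terminal ends of a hypothetical
permutant are unconstrained — only inter-element junctions are tested —
and the native order is always feasible (its junctions are covalent).
Output order of enumerations is lexicographic by label sequence, for
reproducibility.

Topology relations: `identical` (equal label sequences), `circular` (one
is a nontrivial cyclic rotation of the other), `non_circular` (any other
reordering). Permutant design is pure sequence surgery — concatenate
element subsequences in the new order — so length and residue multiset
are preserved by construction and each output position carries its
(source element, source residue) provenance.

## Icosahedral lattices

T = h² + hk + k² for non-negative indices; a census accepts only integers
expressible in that form. Handedness (laevo/dextro) applies only to
chiral lattices (h ≠ k, both nonzero) and is carried as metadata: the
operator set contains rotations only, so it is handedness-agnostic, and
the mapping of laevo/dextro onto (1,2)/(2,1) is a convention the toolkit
exposes rather than asserts.

The 60 rotations of *I* are generated by closing a 5-fold (about an
icosahedron vertex) and a 2-fold (about z) under composition, then
verified against the group-theoretic order census (1 identity, 24
five-fold, 20 three-fold, 15 two-fold elements). Two axis conventions are
offered: `I222` (2-folds along x, y, z; vertices at cyclic permutations
of (0, ±1, ±φ)) and `In25` (the same group conjugated so one 5-fold lies
on z). The icosahedral centre is assumed at the origin; expansion renames
chains `<orig>_<op 00..59>` with copy 00 the identity, and an input that
already looks expanded (≥ 60 chains) is flagged in metadata, not refused.
Maximum diameter is defined over atom centres — twice the largest atomic
radius from the origin — and therefore slightly underestimates map-level
envelope figures.

## Interfaces

Contacts are inter-chain heavy-atom pairs within a cutoff, found with a
k-d tree and tested against an all-pairs oracle. Salt bridges pair
Arg/Lys/His side-chain nitrogens with Asp/Glu carboxylate oxygens across
chains at ≤ 4.0 Å (standard literature convention; deduplicated per
residue pair, minimum distance kept); missing side-chain atoms simply
contribute no candidates. The hydrogen-bond criterion for sheet
augmentation is backbone N···O ≤ 3.5 Å with no angle term — map-derived
models carry no hydrogens, so an angular criterion would be spurious
precision. Bonded residue pairings are grouped into ladders by proximity
in (i, j) index space; orientation comes from the sign of the pairing
progression (ascending i with descending j = antiparallel); ladders need
≥ 3 hydrogen bonds by default. All cutoffs are configurable.

## Chainmail

A ring is an oriented closed polygon through the Cα traces of ordered
member selections, with straight bridging edges across member boundaries.
The Gauss linking number is evaluated with the exact polygonal formula —
for each segment pair, the signed solid angle of the spherical
quadrilateral spanned by the four endpoint vectors (four arcsin terms
plus an orientation sign) — rather than numerical quadrature, so the
4π-normalised sum is an integer up to floating-point residual; a residual
above 1e−6 or an inter-ring approach below 0.5 Å raises instead of
returning a rounded guess. Sign conventions were validated against a
dense midpoint-rule evaluation of the Gauss double integral. Ring
membership is user/config input: the published chainmail figures define
rings pictorially, so the toolkit deliberately does not hard-code a
circuit-detection heuristic.

## Density metrics

Spatial frequency is s = 1/d (Å⁻¹); shells are uniform in s from DC to
Nyquist with values at shell centres, and unpopulated shells (possible
when the shell grid is finer than the Fourier voxel) are dropped rather
than reported as zeros. FSC follows the standard normalised
cross-correlation; the shell R-factor is R = Σ||F_a| − c|F_b||/Σ|F_a|
with the per-shell scale c = Σ|F_a||F_b|/Σ|F_b|² solved in closed form
before the L1 sum — the crystallographic convention with linear per-shell
scaling, adopted because no universal map R-factor definition exists.
No solvent masking is applied before either metric.

Threshold resolution is the first low→high-frequency crossing where map
agreement falls below the threshold (FSC dropping through 0.143; R rising
through 0.5, handled by negation), linearly interpolated between shell
centres and reported as 1/s. A curve that never crosses is flagged
Nyquist-limited; a curve that starts below threshold reports the coarsest
shell rather than inventing a finite resolution.

Sharpening multiplies amplitudes by exp(−B·s²/4), so a "reverse" B of
−200 Å² is passed as b_factor = −200 and amplifies high frequencies;
sharpen(B)∘sharpen(−B) is an exact inverse pair (maps are held in float64
precisely so that the ~10⁷-fold amplification at Nyquist round-trips).
The low-pass filter applies a raised-cosine edge centred on the cutoff
with width in Fourier-voxel units; frequencies in the FFT corners beyond
Nyquist are clamped to Nyquist so a cutoff at Nyquist is the identity.
Map simulation places one isotropic Gaussian per atom, amplitude
proportional to atomic number, with σ = resolution·√(ln 2)/(π√2) so the
atom's Fourier amplitude halves at s = 1/resolution. Subunit averaging
resamples the map with trilinear interpolation at Tᵢ(x) for every masked
reference voxel and averages; transforms that leave the grid raise an
error — values are never silently zero-filled. MRC2014 I/O (mode 2,
float32) goes through gemmi and round-trips grid values bit-exactly.

## Synthetic fixtures: what they emulate, and what they do not

All generators draw from one `numpy` Generator seeded per call, so a
fixture is byte-identical under the same parameters and seed, and every
ground truth is re-derivable by the corresponding analysis (generate →
analyze → recover is tested as a closed loop).

* `make_three_element_fold` emulates only the *anchor geometry* of a
  folded three-element protein: the six C-anchor→N-anchor distances are
  constructed exactly (last-residue anchors on a circle, first-residue
  anchors on the perpendicular axis), defaults 5 Å for bridgeable
  cross-junctions and 42 Å for the buried N-terminus, with element
  lengths 168/73/90 of the 331-residue reference chain. The inter-anchor
  paths are deterministic space-filling wiggles, not protein-like
  backbones — the topology analysis reads only the anchors.
* `make_toy_capsid` places T placeholder subunit blobs at distinct
  positions strictly inside one asymmetric unit of a 100 Å sphere; it
  exercises symmetry expansion and census arithmetic, not packing,
  quasi-equivalent conformational differences, or real subunit shapes.
* `make_ring_set` provides canonical links (Hopf, chains, unlinked sets)
  and a 12-ring icosahedral chainmail: rings of angular radius 33° about
  the 5-fold axes of a 50 Å icosahedron, woven by pushing each ring
  radially in/out at its crossings. The over/under choice at a crossing
  point x between rings i, j is the sign of x·(vᵢ×vⱼ), which is
  automatically antisymmetric between the two rings and opposite at the
  pair's two crossings — yielding |Lk| = 1 for all 30 adjacent pairs and
  a connected catenation graph, the topology (not the geometry) of a real
  capsid chainmail.
* `make_map_pair` builds two noisy realizations of a strictly
  band-limited white random field (the boundary sphere itself carries no
  signal, so the FSC drop sits exactly at 1/band_limit); the requested
  SNR is the real-space signal/noise variance ratio. It emulates
  half-map FSC behaviour, not cryoEM image formation — no CTF, no
  B-factor envelope, no masking effects.
* `make_sheet_pair` places backbone atoms at idealised pairing geometry
  (N···O 2.2 Å between partners, >3.5 Å otherwise), each paired residue
  contributing two hydrogen bonds; it is a detector fixture, not a
  physical β-sheet model.

Passing tests on these fixtures demonstrate correctness of the
*computations* under known ground truth; they do not validate behaviour
on experimental maps or models (partial occupancy, anisotropy,
non-cubic sampling, modelling error).

## Problem sizes and numerical choices

The test and acceptance workloads use 48³–64³ voxel grids, 24–32 shells,
72–240-vertex rings and ≤ 500-atom contact fixtures — sizes at which
every closed-loop check (including the 10-seed resolution-recovery sweep
and the 66-pair chainmail graph) completes in seconds while still
exercising the same code paths as production-size data. Grids are held in
float64; shell curves clip FSC to [−1, 1] against round-off; group
closure, operator identity and linking integrality use absolute
tolerances of 1e−8–1e−6 as stated per operation; tie-breaks (altloc
order, lexicographic topology enumeration, chain renaming on expansion)
are deterministic by construction.

## Known limitations

* Junction feasibility is a pure distance criterion; it does not model
  linker sterics, and it treats the native structure as rigid.
* Sheet-ladder orientation is inferred from residue-index progression
  only; bifurcated or bulged ladders may merge or split near the ≥ 2
  index-step grouping radius.
* The catenation analysis requires geometrically clean rings; curves
  approaching within 0.5 Å must be re-built (e.g. from Cα traces of
  clashing models) before linking.
* `In25` fixes the 5-fold on z but leaves the azimuthal phase to the
  generator's closure order; compose with a z-rotation if a specific
  in-plane alignment is required.
* Non-cubic voxels and non-orthogonal cells are out of scope for volume
  I/O.
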