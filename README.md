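# capsidkit

Structural analysis of HK97-fold ("Johnson-fold") icosahedral virus
capsids, for structural virologists and cryoEM methodologists. The toolkit
covers five connected analyses that together characterise how a tailed
phage builds a stable shell from one major capsid protein (MCP) and an
optional cement/decoration protein (CP):

* **Fold topology.** The Johnson fold decomposes into three
  sequence-contiguous structural elements (N-, β-, α-). A topology is
  their N→C order; permuting *k* elements while preserving each element's
  polarity gives *k*! candidates. Geometry prunes them: a junction
  E<sub>i</sub>→E<sub>j</sub> is buildable only if the Cα of
  E<sub>i</sub>'s last residue lies within a linker-bridgeable distance
  *d*<sub>max</sub> of the Cα of E<sub>j</sub>'s first residue in the
  folded structure. With the N-element's N-terminus buried ~42 Å from the
  other elements' C-termini, 3! = 6 candidates collapse to 2! = 2 — the
  two topologies actually observed in nature. The module also designs
  permutant sequences (cut-and-paste element swaps) with full per-residue
  provenance.
* **Icosahedral lattices.** Caspar–Klug arithmetic
  T = h² + hk + k², the subunit census (60T subunits = 12 pentons +
  10(T−1) hexons, T quasi-equivalent conformers per asymmetric unit), the
  60-element rotation group of *I* in documented axis conventions, and
  expansion of an asymmetric unit to the full shell.
* **Subunit interfaces.** Inter-chain atomic contacts (k-d tree), salt
  bridges (Arg/Lys/His N ··· Asp/Glu O ≤ 4 Å), and β-sheet augmentation
  detected as inter-chain backbone N···O hydrogen-bond ladders with
  parallel/antiparallel orientation.
* **Chainmail catenation.** Closed rings built from Cα traces of
  P-domain/E-loop circuits are tested for topological interlocking via
  the Gauss linking number, evaluated *exactly* for polygons as a sum of
  signed solid angles over segment pairs; the pairwise links assemble
  into a catenation graph whose connectivity answers "is the shell one
  interlocked chainmail?".
* **Map metrics.** MRC2014 volume I/O, Fourier shell correlation
  FSC(s) = Re⟨F<sub>a</sub>F̄<sub>b</sub>⟩/√(⟨|F<sub>a</sub>|²⟩⟨|F<sub>b</sub>|²⟩),
  per-shell amplitude R-factor after closed-form linear scaling,
  threshold resolution estimation (FSC = 0.143, R = 0.5), B-factor
  sharpening exp(−B·s²/4), cosine-edge low-pass filtering, Gaussian map
  simulation from a model, and transform-driven local averaging of
  quasi-equivalent subunits.

Every analysis is exercisable without downloads: `capsidkit.synthetic`
generates seeded fixtures with known ground truth (a fold with controlled
junction geometry, toy capsids, interlocked ring sets, band-limited map
pairs, ideal sheet pairings).

## Worked example

Prune the six candidate topologies of a three-element fold whose
N-terminal anchor is buried 42 Å away from the other elements:

```
$ capsidkit fixtures --kind three_element_fold --seed 1 -o fx/
$ capsidkit topology --structure fx/fold.pdb --partition fx/partition.toml \
      --compare N,alpha,beta
order            junction     distance_A  junction_feasible  order_feasible
N-alpha-beta     N->alpha     5.00        True               True
N-alpha-beta     alpha->beta  5.00        True               True
N-beta-alpha     N->beta      5.00        True               True
N-beta-alpha     beta->alpha  5.00        True               True
alpha-N-beta     alpha->N     42.00       False              False
...
# 2 feasible of 6
# N-beta-alpha vs N-alpha-beta: non_circular
```

Reading: every junction that would place an element *before* the
N-element needs a 42 Å linker and is infeasible at the default
d_max = 20 Å, so only the two orders starting with N survive, and the
swap of β and α between them is a non-circular permutation. Lattice
arithmetic for the T = 7 shell the fold belongs to:

```
$ capsidkit census --h 1 --k 2
T(1,2) = 7
subunits        420
pentons         12
hexons          60
subunits_per_asym_unit  7
```

The same analyses are available as a library (`fold_topology`,
`capsid_lattice`, `chainmail`, `density_metrics`, ...) and as config-driven
pipelines (`capsidkit run --config analysis.toml`, see
`capsidkit.workbench`).

## Scope

No model building or refinement, no particle processing (picking, CTF,
orientation search, reconstruction), no electrostatic surface rendering.
Element boundaries and ring memberships are user input, matching how they
are defined in practice.
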