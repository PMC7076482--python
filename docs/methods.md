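# Methods

This note records the models implemented in `pitmem`, the assumptions they
make, the default parameters and why they were chosen, and what the
synthetic membranes do — and do not — share with real pit membranes.

## Deposition model

Fibrils are straight, rigid, horizontal circular cylinders. A candidate
pose is drawn with uniform centre over the tile and uniform orientation in
[0, π); the axis segment is truncated to the tile. Dropped vertically, the
candidate stops at the largest of the plate height (one radius) and the
per-neighbour contact heights `z_j + sqrt((r_i+r_j)² − d_xy²)`, where
`d_xy` is the in-plane distance between axis segments — exact for
horizontal cylinders, which is why the model forbids out-of-plane tilt.
Settled fibrils never move again: there is no rolling, bending or
post-deposition compaction. Contact bookkeeping uses a relative tolerance
of 1e-6 of the diameter; ties in first-contact height resolve to the
earliest-deposited neighbour.

**Density control.** First-contact deposition of long thin rods produces
mats far too open (solid fraction ≈ 0.05, constrictions ≫ 20 nm). The
generator therefore draws `candidates_per_step` independent poses per step
and keeps the lowest-resting one. This preserves the rigid first-contact
rule while acting as the "deposition sequence" dial of the underlying
deposition technique. With the defaults below it yields solid fractions of
~0.25–0.32.

**Defaults** (all configurable): tile 500 × 500 nm, fibril diameter 20 nm,
fibril length 1000 nm (twice the tile edge, truncated at the tile),
`target_count = 200`, `candidates_per_step = 100`, giving mats ~270–340 nm
thick. The calibration target was morphological: the pooled median
constriction diameter of ten seeded default mats is ~14 nm, inside the
5–20 nm range reported for fresh angiosperm pit membranes, with thickness
near the ~300 nm literature mean. These are calibration choices, not
measured fibril statistics.

`volume_fraction` treats fibrils as capless finite cylinders and evaluates
the union on a midpoint grid (default resolution: a sixth of the smallest
diameter), so tangent fibrils are never double-counted. Deposited
geometries cannot interpenetrate, which is why the running solid-volume
estimate during volume-fraction-targeted deposition may simply sum
cylinder volumes.

## Voxelisation and pore space

A voxel is solid when its centre lies within one radius of a fibril axis
segment (implemented as a union of spheres sampled every half voxel along
the axis; the sampling error is far below a tenth of a voxel). The grid
spans the tile laterally and the mat thickness vertically; a guard warns
when the voxel exceeds a quarter of the smallest fibril diameter. The
default voxel is 2.5 nm (an eighth of the fibril diameter).

Pores are watershed basins of the fluid-phase Euclidean distance
transform, seeded from h-maxima with h equal to one voxel — a maximum must
rise at least one voxel above its saddles to own a pore, which keeps the
segmentation stable under refinement. A pore's `diameter` is its largest
inscribed sphere (twice the basin's distance-transform peak), the standard
local-thickness notion of pore size; this choice guarantees the invariant
that no constriction is wider than either of its pores, because the saddle
value is bounded by the basin peaks. The volume-equivalent sphere diameter
is stored alongside. Constrictions are ridge saddles between adjacent
basins: diameter `2·dt` at the face maximising the smaller of the two
adjacent distance values.

Path analyses treat the two z-faces as inlet and outlet and the lateral
faces as walls. `through_path_count` is the smaller of the unit-capacity
max-flows inlet→pore and pore→outlet over constrictions at least
`min_diameter` wide (default one voxel); a pore's direct attachment to a
face counts as a single wide opening. The obstruction index is
`1 − bottleneck/diameter` clamped to [0, 1], where the bottleneck is the
widest-path (maximum-spanning-tree) inlet→outlet bottleneck through the
pore, and is defined as 1 for pores with no pathway.

## Stokes flow

Steady creeping flow with no-slip on all solid surfaces, a pressure drop
applied between ghost reservoirs half a voxel outside the two z-faces, and
periodic (default) or no-slip lateral boundaries. The discretisation is a
staggered marker-and-cell finite-volume scheme: velocities on faces,
pressures in cells, so discrete continuity is exact up to the linear
solver. Tangential samples next to a wall use a mirror ghost, placing the
no-slip plane on the voxel face (second order on plane walls). The
symmetric saddle system, scaled to voxel units so all entries are O(1), is
solved with MINRES under diagonal preconditioning (the MAC pressure Schur
complement is spectrally close to identity, so the pressure block needs no
preconditioner). Isolated fluid pockets not connected to either face are
excluded from the solve — they carry no flow; non-percolating geometries
return a flagged zero field rather than raising.

Validation: the plane-slit profile is reproduced essentially to machine
precision, the Hagen–Poiseuille rate to ~1%, and the permeability of a
transverse square cylinder array at solid fraction 0.3 lands within ~13%
of the Drummond–Tahir closed-form series (grid-refinement shows the
remaining gap is mostly the oracle's truncation, not the solver). The
effective drop length on these fixtures is `(nz+1)·h` because the ghost
pressures sit half a voxel outside the grid; the Darcy permeability
reported by `summarize_flow` uses the membrane thickness `nz·h`, an O(1/nz)
convention difference that the fixtures account for explicitly.

The Reynolds number is `ρ·v̄·d_f/μ` with `d_f` the fibril diameter
(particle scale) and `v̄` the mean interstitial through-thickness velocity
`Q/(A·ε)`. Per-pore flux is the z-projected flow through a pore's voxels
averaged over the z-slices it occupies, normalised by the total rate.

**Problem sizes.** The package's desk-scale defaults for flow-bearing runs
are 5 nm voxels on the full 0.5 µm tile (≈ 5·10⁵ cells, ~2·10⁶ unknowns)
or 2.5 nm voxels on a quarter tile; structure-only analyses (distance
transform, watershed, constrictions) use 2.5 nm on the full tile. A full
tile at 2.5 nm would require ~1.6·10⁷ flow unknowns, which diagonal-MINRES
cannot turn around interactively; the scaled grids change the measured
permeability by a few per cent on fixtures and do not move the creeping-
flow or morphology conclusions.

## Mechanics

`cox_modulus` returns `v_f·E_f/3` exactly — the shear-lag result for an
ideal planar network of long, randomly oriented fibres.

The direct simulation meshes each fibril into 3D Euler–Bernoulli beam
elements (circular section from the fibril diameter, Poisson ratio 0.3 for
torsion) split at every fibril–fibril contact. A contact is a single
shared node at the midpoint of the closest-approach segment — a rigid weld
transmitting forces and moments; bond compliance is not modelled.
Coincident breakpoints (e.g. a fibril ending exactly on another) merge
into one node. Grips collect nodes within one fibril diameter of the two
opposite tile edges along the tension axis and are fully clamped — this
also removes the free torsion spin of an uncontacted spanning fibril.
Loading is displacement-controlled in equal strain increments; each step
is a linear-elastic solve, after which elements whose axial strain exceeds
the failure strain are deleted (quasi-static fracture; no plasticity).
Fragments no longer tied to both grips are dropped from the system, and a
specimen whose grips disconnect is reported truncated and `failed`, not an
exception. Without a failure strain the response is exactly linear. An
equi-biaxial `uniform_stretch` variant pulls all four edges outward.

Nominal stress uses tile width × mat thickness; the effective modulus is
the first-step secant. For dense mats (v_f ≥ 0.2) it falls within an
order of magnitude of the Cox estimate, as expected: welds, finite fibril
length and out-of-plane waviness of the load paths make the discrete mat
softer than the ideal long-fibre limit. Moisture effects enter only
through the user-supplied `E_f`.

## Pipeline

The YAML config is validated strictly (unknown keys rejected); physical
quantities may carry unit suffixes ("20 nm", "1 kPa", "9 GPa") — the
nm-geometry / SI-solver boundary is the likeliest silent-error source, so
units are explicit at the interface and converted once. Every stage is
seeded; a config plus its seed list reproduces every output number, and a
failing seed is recorded in its report entry without aborting the batch.
Artifacts: fibril tables as CSV with a JSON sidecar, pore graphs as
JSON/CSV, fields as legacy-ASCII VTK and HDF5.

## What the synthetic membranes are not

The generator reproduces layered, randomly oriented, mutually supporting
fibril mats with realistic thickness and constriction statistics. It does
not model fibril bending or post-deposition compaction (real membranes are
denser and their pore walls are not perfect cylinder unions), bundling of
microfibrils, chemistry (pectin gels, surfactant coatings) that modifies
effective pore sizes, capillary or two-phase effects during flow, or
fluid–structure coupling (fibrils are rigid during flow). Passing tests
therefore validate the computational chain and its scaling behaviour on
this idealised morphology, not species-specific quantitative predictions.

One documented property of the idealised mats differs from the qualitative
expectation that motivated the per-pore analysis: because a pore's flux
*fraction* is extensive (it grows with pore cross-section), pore size
ranks flux at least as well as the size-normalised openness
`1 − obstruction index` when all watershed basins are pooled. The
phenomenon of interest is nevertheless present: among resolvable pores
(diameter ≥ 15 nm) most membranes contain top-quartile-diameter pores
whose flux is below the population median — large pores whose pathways are
obstructed contribute little to transport. The test suite asserts both
statements separately.

## Numerical choices

- Contact tolerance 1e-6·diameter (relative); deposition RNG is
  `numpy.random.default_rng(seed)`; identical parameters and seed give
  bit-identical fibril tables, and a longer run extends a shorter one.
- MINRES tolerance default 1e-8 (fixtures converge well below it; dense
  membranes are run at 1e-5–1e-7 where mass imbalance stays below 0.1%).
- Watershed merge depth: one voxel. Constriction diameters are quantised
  by the grid; refinement halving the voxel moves fixture constrictions by
  less than one coarse voxel.
- Degenerate inputs: empty networks voxelise to all-fluid grids; all-solid
  grids give empty pore graphs; zero pressure drop leaves the permeability
  undefined and flagged; beam elements shorter than 1e-6 nm are merged.
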