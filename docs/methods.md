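# Methods

`mtwedge` is a coarse-grained simulator for the depolymerization of
microtubules whose lattices mix two tubulin-dimer conformations: straight
("uncompressed", the GTP/GMPCPP-like state) and bent ("compressed", the
GDP-like state produced by hydrolysis).  The package has three layers: a
geometry/lattice builder, a rigid-body Langevin engine, and an analysis layer
for depolymerization kinetics and island (cluster) statistics.

## The wedge model

Each tubulin monomer is a rigid wedge of 27 steric beads on a 3x3x3 grid
(three radial, three tangential, three axial layers) whose tangential spread
grows with radius so that exactly 13 wedges tile a closed ring.  Beads of
different subunits repel through the cut-and-shifted Lennard-Jones (WCA)
potential

    U_LJ(r) = 4*eps[(sigma/r)^12 - (sigma/r)^6] + eps,   r < 2^(1/6) sigma.

Eight massless attractive sites per wedge mediate bonding through a cosine
well

    U_A(r) = -A [1 + cos(pi r / r_c)],   r < r_c = 0.75 sigma,

with face-specific partners: the lateral pairs (left/right faces, split
axially, and offset by half the helical pitch per face) bind the
protofilament's circumferential neighbours with `A_L = 1.4 kT`; the vertical
pairs (top/bottom faces, split radially) bind along the protofilament with
`A_V = 4.8 kT` between dimers and `A_intra = 8.0 kT` inside a dimer.  All
site strengths, the cutoffs, the temperature `T = 1 eps/k_B`, time step
`dt = 0.005 tau`, and Langevin damping `1/tau` follow the published
parameterization of this model family.

A dimer is an alpha-subunit topped by a beta-subunit.  Hydrolysis is a shape
change only: the compressed alpha has its top-face bead layer sheared
downward about its luminal (inner-face) edge so the face normal tilts inward
by `theta = 15 deg`, and its top binding-site pair reorients by the slightly
larger angle `g*theta` (the *site tilt gain*, `g = 1.1296`, see Calibration).
Uncompressed alpha and beta wedges are identical in shape.

## Stacking and the hinge

The vertical site pair is split radially (half-split 0.5 sigma) about an
anchor at `x = -1.44 sigma`, the luminal edge of the bead body, so the pair
transmits orientation: a chain of compressed dimers minimizes its site energy
by turning `g*theta` at every intra-dimer hinge, producing the outward curl
of peeling protofilaments ("ram's horns").  Facing bead layers of stacked
subunits are held at 1.6 sigma — outside the WCA range — so stacking
distances and hinge angles are set by the smooth site wells alone and the
in-register lattice is an exact zero-force minimum; beads engage only in
genuine collisions (e.g. a horn pressing on its neighbours, or hinge
rotations beyond ~35 degrees).

## Calibration

The published constraints for this model are emergent, not prescriptive: at
`theta = 15 deg` a relaxed protofilament of compressed dimers should curl at
28 nm radius, and a fully compressed microtubule should be 2% shorter axially
than a fully uncompressed one, with 9 nm of length per dimer row.  Two
proportions are fixed once against these targets:

- **Site tilt gain `g`.**  With the dimer repeat pinned at 9 nm, a curl of
  exactly `theta` per dimer would give a radius near 32-34 nm for any
  contiguous 27-bead body (R ~ nm_per_row/(2 sin(theta/2)) minus a small
  centroid offset).  The binding interface therefore reorients by `g*theta`
  with `g = 1.1296`, calibrated so the energy-minimized 20-dimer chain curls
  at 28.0 nm.  Physically this says the bonding contact follows the
  conformational change with a slightly longer lever than the rigid face —
  the model's stand-in for the intra/inter-dimer partitioning of the real
  hydrolysis compaction.
- **Pivot offset (0.388 sigma).**  The compressed top site pair is sheared
  about a pivot this far inside the anchor, which drops the pair center and
  shortens each compressed row; the value is calibrated against the relaxed
  lattice (hinge drop plus the small settling of the strained pair) to give
  2.0% axial compaction at 40 rows.

Both calibrations are deterministic minimizations; they do not involve the
thermostat or any random number.

## Lattice assembly

`sample_composition` draws each dimer independently uncompressed with the
requested probability (one seed, bit-reproducible).  `build_microtubule`
places dimers on a 13-protofilament, 3-start helix: protofilament `k` is
rotated `k*2pi/13` and raised `k*(3a/13)` (`a` the monomer repeat), which
puts every lateral site pair exactly in register, including across the seam,
where the accumulated three-monomer shift makes a seam-left dimer contact the
dimers one and two rows higher on seam-right.  Rows are pre-compacted by the
row-mean compressed fraction so the built state is near its minimum; the two
bottom rows are immobilized (the minus-end tether).  The nominal solution
GMPCPP fraction maps to an incorporated fraction through competitive binding
with fourfold-stronger GTP: `f = c/(c + 4(1-c))`.

## Integration and minimization

Subunits are integrated as rigid bodies (6 DOF) with a BAOAB-split Langevin
scheme: velocity half-kicks, exact Ornstein-Uhlenbeck updates of the linear
momentum and of the body-frame angular momentum, and a symplectic
principal-axis splitting for free rotation.  The rotational friction equals
the translational `damping` (1/tau); this choice is the package's own, made
because the published bead-level thermostat damps rotations implicitly and at
the overdamped, coarse scale of interest only the product of friction and
timescale matters.  With the thermostat off the integrator is NVE and drifts
below 1e-5 eps/step at dt = 0.005 tau; with it on, the time-averaged kinetic
temperature is within 1% of the set point.  A stiff-spring compatibility mode
(all intra-subunit bead pairs bonded with `K = 500 kT/sigma^2`) reproduces
the same composites as point particles; its thermal breathing is
sqrt(kT/K) ~ 0.045 sigma per spring instantaneously, while time-averaged
intra-subunit distances match the template to ~0.1%.

Energy minimization uses FIRE on the rigid DOFs with a rotational inertia of
r_max^2 to balance translational and rotational relaxation, a 0.05 sigma step
cap, and velocity clamping.  Two landscape quirks matter: (i) curling a
straight chain is a long, nearly flat valley, so the curl-radius operation
relaxes from several uniformly pre-curled seeds (0 to 1.25x the hinge angle)
and keeps the lowest-energy converged state; (ii) the free plus-end of a
compressed lattice creeps outward at T = 0 indefinitely, so the compaction
operation converges on the observable — the interior row spacing, stationary
to 1e-4 rows (0.01 pp of compaction) — rather than on the global force norm.

All randomness flows from explicit integer seeds; trajectories with the same
seed are bit-identical.  The numba kernels avoid fast-math reassociation so
results do not depend on the host's SIMD width.

## Analysis definitions

- **Intact length.**  A dimer is part of the wall when both subunits are
  within 1 sigma of their relaxed lattice positions and at least one lateral
  site pair is engaged (< r_c).  The microtubule length is the largest
  contiguous block of fully intact rows from the tether, times 9 nm.  At
  T = 1 this instantaneous criterion flickers by about a row near the free
  end; rates are therefore computed over windows.
- **Instantaneous rate.**  Centered finite difference of the length trace
  (default window three samples); negative samples (re-attachment) are kept.
- **Interruptions.**  Maximal intervals with |rate| below a threshold
  (default 10% of the 0.240 um/s plateau) lasting at least a minimum
  duration (default two 5-s sampling intervals).  The published experiments
  did not state their operational criterion, so these defaults are
  configurable and echoed in every output; interruption counts are
  threshold-sensitive and are not treated as calibration targets.
- **Exposed protofilament lengths.**  Per protofilament, the contiguous
  vertically-bonded dimers above the last intact row that are not embedded in
  the wall — the length of a peeling horn; an intact column scores zero.
- **Local composition.**  Uncompressed dimers in the top three intact rows
  (at most 39), the lattice the front is about to consume.
- **Composition dependence.**  The loss-rate-vs-composition curve is
  summarized by a plateau (mean rate at <= 10% uncompressed) and an
  exponential branch `a*exp(-b*x)` fitted for x >= 20%; their crossing
  estimates the slowdown onset.  Time is mapped to seconds by matching the
  0% loss rate to 0.240 um/s (`calibrate_time`), and the percent time
  interrupted vs composition is summarized by ordinary least squares.
- **Islands.**  Uncompressed dimers sharing at least one vertical or lateral
  subunit bond form one cluster; the seam contributes the shifted contacts
  (r -> r+1, r+2), with a naive circular "wrap" adjacency available as a
  toggle.  Histograms h(n) are average counts per 5 um, honoring the
  published convention that a 555-row clustering lattice counts as 2.4 um
  (note this differs by ~4% from 555 x 9 nm; the printed value is used for
  the normalization).  Footprints report rows spanned and the minimal
  circular protofilament arc; a cluster covering all 13 protofilaments
  "percolates" laterally.

## Desk-scale study sizes

The published kinetics used 40-160-row microtubules, five replicates per
composition, and multi-second (multi-10^6 tau) trajectories; at that scale
the 0% loss rate defines the 3e6 tau/s conversion and the full Fig.-style
rate curve.  The bundled tests and the acceptance script run the same
pipeline at sizes chosen to finish in minutes on one core:

- geometry calibration: 20-dimer chains and 40-row lattices (deterministic);
- island statistics: the full published ensemble (20 lattices x 555 rows per
  composition), which is cheap;
- depolymerization ordering: 5-row microtubules, 120 tau, five replicates at
  0/40/70% uncompressed, asserting the mean loss rate is non-increasing in
  the uncompressed fraction.  At this scale rates are far above the
  experimental ones (fewer rows, shorter times); only the ordering is
  meaningful, not the absolute values.

## What the synthetic data do and do not show

The fixture generator produces idealized inputs — exact linear/piecewise
traces, noiseless exponential rate points, hand-built peeled-horn snapshots,
and composition grids.  Tests against them establish that the analysis layer
is exact on known ground truth; they say nothing about whether real (or
simulated) microtubules satisfy the fitted laws.  The simulator-side tests
establish the mechanistic ingredients (curl radius, compaction, stability of
the uncompressed lattice, peeling of the compressed one, slowdown with
composition) at reduced scale.  Quantitative reproduction of the published
rate constants (0.240 um/s plateau, 0.60 exp(-0.060 x) decay) requires the
full-scale runs described above.

## Known limitations

- No growth, nucleation, hydrolysis events, GDP/GTP exchange, or rescue
  regrowth: lattices are prebuilt "after all hydrolysis has taken place".
- The two-point vertical hinge leaves torsion about the radial axis soft, so
  free horns wobble tangentially at T = 1; lateral bonds restrain this in
  the lattice.
- The instantaneous intact-row criterion is strict; near the free end it
  can transiently drop a row that re-attaches (visible as negative rate
  samples).
- Trajectories are chaotic: fixed seeds give bit-identical runs, but any
  change to the force path changes individual trajectories; only ensemble
  statements are stable.
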