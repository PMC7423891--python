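# mtwedge

Coarse-grained simulation and analysis of microtubule depolymerization with
mixed tubulin-dimer conformations.

Microtubules are 13-protofilament tubes of alpha/beta-tubulin dimers.  After
GTP hydrolysis the alpha-subunit compacts, storing strain that drives the
catastrophic shrinkage of the lattice through outwardly curling
protofilaments ("ram's horns").  Dimers carrying a slowly hydrolysable
nucleotide (GMPCPP, a GTP analog) stay straight; islands of such uncompressed
dimers embedded in a GDP lattice slow depolymerization, pause it
("interruptions"), and change the end morphology from ram's horns to blunt —
the mechanism by which GTP-tubulin remnants are thought to seed rescue.

`mtwedge` implements the wedge model of this system: each tubulin monomer is
a rigid wedge of 27 WCA beads with eight short-range attractive sites
(cosine well `U_A(r) = -A[1 + cos(pi r/r_c)]`, `r_c = 0.75 sigma`; lateral
`A_L = 1.4 kT`, vertical `A_V = 4.8 kT`, intra-dimer `A_intra = 8 kT`).
Hydrolysis is represented by compressing the alpha-wedge by `theta = 15 deg`,
calibrated so an isolated protofilament of compressed dimers curls at 28 nm
radius and a fully compressed lattice is 2% shorter axially (9 nm per dimer
row).  Microtubules of any uncompressed fraction are assembled on the
13-protofilament, 3-start helix (seam included), tethered at the minus end,
and evolved with a rigid-body Langevin integrator (`T = 1 eps/k_B`,
`dt = 0.005 tau`, damping `1/tau`).  The analysis layer turns trajectories
into length traces, instantaneous loss rates, interruption statistics,
exposed-protofilament maps, and island (cluster) statistics with per-5-um
size histograms, footprints, and lateral-percolation detection.

For whom: anyone studying microtubule dynamic instability mechanisms in
silico — or who needs a compact, fully scriptable patchy-particle
self-assembly testbed with a complete kinetics-analysis pipeline.

## Worked example

```python
import numpy as np
from mtwedge import (ModelParameters, sample_composition, run_depolymerization,
                     length_trace, protofilament_equilibrium_radius,
                     axial_compaction, find_clusters)

params = ModelParameters()          # theta = 15 deg, A_L = 1.4 kT, ...

# geometry calibration checks
r = protofilament_equilibrium_radius(20, params)
c = axial_compaction(params, n_rows=12)
print(f"curl radius {r:.1f} nm, axial compaction {100*c:.2f} %")

# a desk-scale depolymerization run: 8 rows, 0% vs 70% uncompressed
for frac in (0.0, 0.7):
    cfg = sample_composition(8, frac, seed=1)
    traj = run_depolymerization(cfg, params, duration_tau=150.0,
                                snapshot_cadence=10.0, seed=2)
    tr = length_trace(traj)
    print(f"{frac:.0%} uncompressed: intact rows {tr.meta['rows'].tolist()}")

# island statistics at 40% uncompressed
cfg = sample_composition(555, 0.40, seed=7)
sizes = find_clusters(cfg).sizes
print(f"40%: {len(sizes)} islands, largest {sizes.max()} dimers")
```

prints (exact trajectory numbers depend on the seeds):

```
curl radius 28.0 nm, axial compaction 2.01 %
0% uncompressed: intact rows [8, 8, 7, 7, 7, 6, 7, 7, 7, 5, 4, 3, 5, 4, 4, 4]
70% uncompressed: intact rows [8, 8, 7, 7, 7, 7, 7, 7, 7, 5, 7, 3, 6, 7, 5, 5]
40%: 704 islands, largest 64 dimers
```

The fully compressed (0%) microtubule progressively sheds its free rows
through curling protofilaments, while the 70% lattice mostly breathes at the
tip (the transient dips are re-attachments, which the rate analysis keeps as
negative samples).  Averaged over replicates the mean loss rate is
non-increasing in the uncompressed fraction — the composition dependence
that the full analysis layer (rate-vs-composition fits, interruption
statistics) quantifies.  A command-line interface
(`mt build|simulate|analyze|clusters|fixture`) wraps the same library for
shell use.

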