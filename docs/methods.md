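# Methods

## Problem and scope

`smdfan` automates multidirectional constant-velocity steered-MD (SMD)
campaigns on two-body complexes.  Conventional SMD pulls along a single
coordinate and can miss mechanical anisotropy — the dependence of rupture
forces and unbinding pathways on the pulling direction.  The toolkit covers
three stages: (i) generating a fan of pulling directions over the hemisphere
anchored on the inter-center-of-mass axis of the complex, (ii) rendering
ready-to-run NAMD and GROMACS inputs per direction with replica support, and
(iii) analyzing the resulting force traces (rupture force, force–distance,
replica mean ± SD, hydrogen-bond counts).  A toy steered Brownian-dynamics
engine closes the loop so the full pipeline is testable at desk scale.

## Direction geometry

The principal axis is the unit vector from the fixed group's mass-weighted
center of mass (COM) to the pulled group's COM.  Mass weighting is the
standard convention; a geometric-center option exists for coarse models with
uniform beads.  Around the axis a right-handed orthonormal frame
(e1, e2, axis) fixes the azimuthal origin:

    e1 = normalize(z × axis),   e2 = axis × e1,

falling back to the unit projection of x into the transverse plane when the
axis is within ~2.6° of ±z (so axis = +z gives the canonical e1 = x,
e2 = y).  The fallback is a projection rather than a cross product so the
canonical frame comes out axis-aligned; any deterministic convention would
do, since no physical feature distinguishes azimuths.

Each direction is

    v(θ, φ) = cosθ·axis + sinθ·(cosφ·e1 + sinφ·e2),

with θ the polar angle from the axis and φ the azimuth.  The default grid
θ ∈ {0°, 45°, 90°} × φ ∈ {0°, 90°, 180°, 270°} collapses the fourfold-
degenerate pole and yields nine distinct directions covering the hemisphere
on the pulled side.  Duplicates are any pair within 10⁻⁶ rad — far below
any sensible grid spacing.  θ > 90° is allowed for full-sphere fans.

## Engine input generation

Per direction, a subdirectory named by the angle label holds the engine
input(s), the auxiliary file the engine needs, and a `run.sh` looping over
replicas.  NAMD runs use the standard column conventions: fixed atoms
flagged in the B-factor column of a reference PDB (`fixedAtomsCol B`),
SMD atoms in the occupancy column.  GROMACS runs use the pull code with
`pull-coord1-geometry = direction` and freeze groups for the fixed protein;
freeze groups need no topology edit, at the documented cost that frozen
atoms are excluded from pressure coupling.  Replica r uses engine seed
`base_seed + r` (recorded in the manifest); for NAMD the replica index
enters the Tcl config through an environment variable, for GROMACS each
replica gets its own `.mdp` differing only in `gen-seed`.

Spring constants and velocities are stored engine-native (kcal mol⁻¹ Å⁻²
and Å per timestep-unit for NAMD; kJ mol⁻¹ nm⁻² and nm ps⁻¹ for GROMACS)
and never silently converted.  Numbers are written with a formatter that
uses fixed six decimals when exact and shortest-repr otherwise, so rendered
files are both human-readable and bit-exact under re-parsing.

## Trace analysis

All forces are converted to pN (69.4786 pN per kcal mol⁻¹ Å⁻¹, 1.66054 pN
per kJ mol⁻¹ nm⁻¹) so both engines and AFM experiments are directly
comparable.  The primary force coordinate is the projection of the force
vector on the pulling direction; the magnitude is available as an option.

The rupture force is the global maximum of the unsmoothed force series
(earliest time on ties).  Smoothing — a centered running mean, default off
for analysis and 51 samples for plots — never feeds the rupture statistic
unless explicitly requested.  Replica aggregation interpolates each trace
linearly onto a uniform grid spanning the *intersection* of the replica time
ranges (step = smallest native sampling interval), so no values are
fabricated outside any trace's span; the ensemble SD uses the n−1
denominator, appropriate for the typical five replicas.  Duplicate time
stamps from restart overlaps keep the last occurrence with a warning.

Hydrogen bonds use the de-facto standard geometric criterion: donor–acceptor
distance ≤ 3.5 Å and D–H···A angle ≥ 150°, on caller-supplied donor/acceptor
lists, optionally restricted to inter-fragment pairs.  The counting kernel
is vectorized; tests pin it to an explicit O(donors × acceptors) double
loop.

## Toy engine

The bundled simulator integrates overdamped (inertialess) Langevin dynamics,

    dr = (F/γ) dt + √(2 k_B T dt / γ) ξ,

with Euler–Maruyama, per-bead friction γ, k_B = 0.0138065 pN Å K⁻¹, and all
internals in pN/Å/ps.  Overdamped rather than full Langevin dynamics keeps
one fewer parameter and an unconditionally simple integrator; the simulator
exists to exercise the analysis surfaces, not to be a physics engine.  The
SMD spring force k(vt − projected COM displacement) is distributed over the
pulled beads proportional to mass; fixed beads never move; breakable bonds
are removed permanently the first step their length exceeds the rupture
length.  The emitted log uses the NAMD SMD line dialect so the standard
parser consumes it unchanged.  Two closed-form limits anchor the physics
tests: a free bead at T = 0 follows r(t) = vt − (γv/k)(1 − e^(−kt/γ)), so
the pulling force relaxes to the terminal drag γv; and a single breakable
bond pulled quasi-statically ruptures at F ≈ k_b(r_break − r0).

## Built-in anisotropic complex and the rupture oracle

`make_anisotropic_complex` builds a pulled four-bead tetrahedron anchored
in a fixed "socket" (a five-bead ring plus center) by six breakable bonds
with very unequal stiffnesses (5.8–20 pN Å⁻¹) and rupture extensions
(2.2–3.2 Å).  The anchors are deliberately *tilted*: bonds parallel to the
inter-COM axis respond identically to every transverse pull of a rigid
cluster, and the azimuthal anisotropy would vanish.  Bond placement,
stiffnesses and extensions were chosen once so that the nine default
directions produce well-separated quasi-static rupture forces (roughly
64–143 pN, adjacent values ≥ ~6 pN apart); temperature (10 K), friction
(5 pN ps Å⁻¹ per bead) and the default pulling protocol (k = 20 pN Å⁻¹,
v = 0.05 Å ps⁻¹, 88 000 steps of 5 fs) keep replica scatter (SD ≲ 3 pN)
and finite-rate bias (≲ 7 pN) small compared to those separations while a
full 9-direction × 5-replica campaign runs in about five minutes on one
CPU.

The independent oracle, `quasistatic_rupture_scan`, is the zero-velocity,
zero-temperature limit of the same protocol: the spring anchor advances on
a fine displacement grid and the total energy (bonds + COM spring) is
minimized (L-BFGS) over all mobile coordinates at each step, warm-started
from the previous minimum so the system follows the adiabatic branch;
over-stretched breakable bonds are removed permanently and the state
re-relaxed.  The rupture force is the maximum spring tension along the
scan.  Relaxation (including cluster rotation) matters: a rigid-translation
scan overestimates transverse rupture forces badly, because the pulled
cluster reorients long before bonds break.  The end-to-end check compares
the rank ordering of campaign mean rupture forces across the nine
directions against this oracle.

## Numerical choices

- Degenerate-axis tolerance: COMs closer than 10⁻⁶ Å (below PDB coordinate
  precision) raise an error rather than produce a garbage axis.
- Unknown element symbols fall back to 12.011 amu with a logged warning, so
  coarse-grained inputs without element columns still work.
- Toy-engine stability: the Euler step requires dt < 2γ/k for the stiffest
  bond; the defaults (dt = 0.005 ps, k = 100 pN Å⁻¹, γ = 5) sit at 1/8 of
  that bound.  Non-finite coordinates abort with the offending step number.
- Oracle scan: ds = 0.05 Å anchor steps, L-BFGS with gtol = 10⁻⁸,
  ftol = 10⁻¹², early exit once every breakable bond is gone and the force
  has relaxed.

## What the toy data do and do not show

The synthetic complex exercises every pipeline surface — direction
generation, input rendering, log parsing, replica statistics, rupture
anisotropy, H-bond counting on scripted trajectories — with known ground
truth.  It does not emulate solvent, electrostatics, force-field detail,
loading-rate dependence over decades, or the microsecond relaxation of real
protein–protein interfaces; passing tests demonstrate the correctness of
the bookkeeping and statistics, not the transferability of any rupture
force to a real system.

## Known limitations

- PDB only (no mmCIF); no topology generation, solvation or equilibration.
- Constant-velocity pulling only; no constant-force mode, no Jarzynski
  free-energy reconstruction (the analysis is deliberately comparative).
- Binary trajectory formats require conversion to multi-model PDB/XYZ
  upstream (e.g. with MDAnalysis).
- The toy engine is overdamped and thermostat-free beyond its noise term.
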