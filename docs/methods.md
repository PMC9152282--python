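# Methods

`voxelrxd` simulates intracellular reaction–diffusion in 3D on neuron
morphologies described, as for electrophysiology, by point-and-diameter
samples.  This note records the model, the numerical choices, and what the
validation experiments do and do not establish.

## Geometry model

A morphology is a tree of unbranched sections, each a run of
`(x, y, z; d)` samples in micrometers.  Electrical state lives on `nseg`
equal arc-length compartments ("segments") per section; extra sample
points are interpolated at compartment boundaries so every frustum belongs
to exactly one segment.  The 3D cell volume is the union of

* one right-circular cone frustum per consecutive sample pair, and
* a *join sphere* at every point where two or more frusta meet, with
  radius equal to the largest incident end radius, clipped to the wedge
  between the incident end faces (the intersection of the half-spaces
  behind each face, which is convex).  When two incident frusta are
  collinear head-to-tail the wedge is degenerate and the sphere is
  dropped.

This join rule smooths bends and branch points with convex pieces.  It is
a deliberate approximation: the fully general clip rule used by the CTNG
family of algorithms depends on taper and intersection angle in ways that
are not recoverable from published descriptions, so voxel-exact agreement
with other implementations at branch points is not expected (the
three-section Y benchmark lands within ~1% of the reference voxel count).
Spines attach to the interior of their dendrite; the neck base is inset
from the dendrite surface by `r_d - sqrt(r_d^2 - r_n^2)` so the neck
cross-section stays inside the dendrite while overlapping it minimally.
When a thin child attaches to the end of a thick parent, the stepped
fixture reproduces the stylized join cone of cable simulators (the child's
first sample carries the parent diameter and tapers to the child diameter
by the midpoint of its first segment).

## Voxelization

The union is discretized on a cubic lattice of edge `dx` anchored at the
padded bounding-box minimum.  Anchoring to the bounding box (rather than
snapping the origin to multiples of `dx`) makes the discretization
translation-invariant — the mesh depends only on shape and orientation —
and removes a systematic artifact in which symmetric fixtures always
landed with their centers exactly on lattice corners, inflating the
orientation-averaged volume error by ~15%.

A voxel is stored when at least one of its 8 corners is inside the union
(boundary points count as inside).  Because every convex solid meets an
axis line in one interval, each solid's voxels are enumerated row by row
with the entry/exit coordinates solved in closed form per lattice line —
the same row structure a seeded flood fill visits, but vectorized and with
no seed search; degenerate lines (extreme taper) fall back to exhaustive
corner tests.  Numerical care that matters: the frustum signed distance
computes the radial component from the explicit perpendicular vector;
the textbook `|pa|^2 - (pa.u)^2` form cancels catastrophically ~100 um
from the origin and jitters the membership of exactly-on-surface points,
which destroys the cross-section uniformity of the mesh.

Stored voxels with all corners inside are interior: volume fraction 1, no
surface.  Surface voxels carry

* a partial volume: the fraction of a uniform `(1 + VR)^3` test-point
  lattice inside the union (`VR = 2` by default; `VR = 1` uses the corners
  only), clamped to at least one point so the volume is never zero;
* a marching-cubes surface area from the corner signed distances
  (classic 15-case table; an `SR^3` subdivision is available but off by
  default, because it does not improve the area for the cost);
* the corner signed distances themselves.

Overlapping solids assign each voxel to the incident segment closest to
the root of the electrical tree, so spine-neck voxels buried in the
dendrite belong to the dendrite.  Voxels that end up with exactly zero
computed surface area remain in the mesh but are excluded from
surface-based kinetics.

Validated behavior (see `tests/test_acceptance.py`): for a 2x5 um cylinder
over random orientations (each spherical angle drawn uniformly), mean
absolute volume error 0.39 um^3 and area error 2.93 um^2 at `dx = 0.5` with
`VR = 1`, converging at ~O(dx^2.2) and ~O(dx^1.2); marching-cubes areas are
underestimates for convex bodies.

## Reaction–diffusion integration

Concentrations are mM, volumes um^3, time ms; 1 mM um^3 = 1e-18 mol =
602214.076 molecules.  Fixed-step integration is operator-split per step:

1. **Reactions and point fluxes, implicitly.**  Each voxel's local ODE
   system is advanced by backward Euler with Newton iteration (absolute
   tolerance 1e-12 mM, at most 20 iterations, initial guess the current
   state; finite-difference Jacobian, or an analytic derivative when the
   rate supplies one).  Point fluxes are mass-based (molecules/ms, or per
   second on request): the same amount enters the cell regardless of `dx`
   and `dt`.  Parameters never change; states react but do not diffuse.
2. **Diffusion by Douglas–Gunn ADI** with Crank–Nicolson weights
   (theta = 1/2): an implicit tridiagonal sweep along x using the full
   explicit y/z update, then half-implicit correction sweeps along y and
   z.  The tridiagonal systems are the precomputed maximal contiguous
   voxel lines per axis.  Line ends are zero-flux (reflective membrane).

The face conductance between lattice neighbours is `D` times the harmonic
mean of their interior volumes over `dx^2` (`D dx` for full voxels).  This
is the one place the scheme deviates from the plainest reading of a
finite-volume stencil: a *uniform* face conductance with partial volumes
breaks the exact reduction of axis-aligned cylinder problems to the 1D
heat equation and produces errors three orders of magnitude larger on the
line-diffusion benchmark.  With the harmonic-mean transmissibility the
benchmark errors are 5.3e-5 / 1.3e-5 / 3.3e-6 mM at dx = 0.5 / 0.25 /
0.125 um (t = 100 ms, dt = 0.025 ms), converging at O(dx^2).  Fluxes are
pairwise antisymmetric in mass form, so total mass is conserved to
round-off for any `dt` (measured drift ~1e-11 relative over 1e5 steps on
the Y geometry) for both uniform conductances and this choice.

Lines of length 1 are solved as 1x1 systems.  The splitting order is Lie
(reactions first, then diffusion); the per-step difference from a dense
Crank–Nicolson solve on the same stencil shrinks faster than O(dt^2)
(dense-oracle test on a 64-voxel block).

## Membrane coupling

Segment membrane currents use the 1D (frusta) lateral areas for electrical
purposes; the 3D marching-cubes areas only apportion each segment's
current across its surface voxels.  Charge-to-mass conversion uses
Faraday's constant; segment concentrations are reported back to membrane
mechanisms as the volume-weighted mean over the segment's surface voxels
(or all voxels with `feedback='all'`, which tracks the well-mixed value
better when diffusion is slow).  The built-in mechanisms are

* classic Hodgkin–Huxley kinetics at 6.3 C (gnabar 0.12, gkbar 0.036,
  gl 0.0003 S/cm^2, el -54.3 mV, v0 -65 mV, nai 10 mM, nao 140 mM — the
  standard squid-axon defaults, stated here because the sodium-accumulation
  benchmark numbers depend on them), with exponential-Euler gates, a
  conductance-implicit voltage update and the sodium reversal recomputed
  from the surface concentration each step via the Nernst equation;
* a constant current clamp;
* an event-driven synaptic mass flux: a production rate `g` (molecules/ms)
  that jumps by a weight per event and decays with time constant tau,
  integrated exactly within each step so the delivered mass is independent
  of `dt` (and of `dx`, being mass-based).  Targets must be surface voxels
  with positive area.

With a 10x10 um soma under 0.1 nA injection, surface sodium after 100 ms
reaches ~13.6 / 11.2 mM (D = 1e-4 / 0.01 um^2/ms) at dx = 0.5 and
~16.1 / 11.2 mM at dx = 0.25, and approaches the well-mixed 1D value as D
grows — the expected surface-shell effect.

## Hybrid 1D–3D simulation

Each section is simulated either on the 3D grid or as part of a branched
1D cable (backward-Euler axial diffusion on segment compartments with
frusta volumes and cross-section-over-distance conductances; backward
Euler rather than Crank–Nicolson because the weak junction coupling
already limits the achievable order there).  Junctions exist only at
section ends.  The boundary voxels of a junction are the single layer of
the 3D section's voxels just inside the plane through the shared end,
perpendicular to the section axis; each exchanges mass with the adjacent
1D segment at rate `D * area * (c_1D - c_vox) / distance`, with
`distance = dx/2 + (segment length)/2` and `area = V^(2/3)`.  The exchange
is computed from the state at the start of the step and both domains then
advance independently (weak coupling); the update is exactly
antisymmetric, so hybrid models conserve mass to round-off.  Large `dt`
can destabilize the junction exchange; no automatic step control is
attempted.

On the 153x2 um three-section benchmark (plug on [70, 83] um, t = 50 ms,
two 1D segments per micron) the maximum error of the volume-weighted
concentration profile is 1.27e-3 mM at dx = 0.25 and 4.5e-4 at dx = 0.125
(reference: 1.21e-3 and 5.17e-4).  One caveat: raising the partial-volume
resolution to VR = 6 does not reduce our junction error (reference drops
to 4.38e-4), because the exact-signed-distance partial volumes here are
already converged at VR = 2; the residual is the lumped distance/area
junction model itself, which is insensitive to VR.

## Validation oracles

Closed forms used as references: the 1D interval (erf) solution with
method-of-images terms for reflective ends, added until a term changes the
result by < 1e-15; the separable box solution for 3D diffusion from a cube;
and the scalar bistable equation `u_t = D lap(u) - u(1-u)(alpha-u)`, whose
plane-wave front speed is `sqrt(2 D) (1/2 - alpha)`.  The wave-front
tracker reproduces the measurement procedure: the front is the farthest 1D
position whose per-segment volume-weighted mean exceeds 1/2 (interior dips
are ignored), and the crossing times of 100 um and 200 um are linearly
interpolated.

## Problem sizes and scaled studies

Orientation studies use 1000 orientations at the single-dx level and 100
per dx for convergence slopes; the wave-speed study runs 5 orientations of
the 251x2 um cylinder at dx = 0.25 (every orientation stays under the 4%
worst-case relative error; the reference mean over 100 orientations is
2.17 +/- 1.09%).  The cube-source benchmark is run at its full size (40 um
domain, t = 20 ms): shrinking the domain or the time violates its premise
that boundary reflections and early-time discretization error are
negligible, and the 0.1% bound genuinely fails there.  Conservation runs
1e5 steps per dt.  The spine study uses dx = 0.05 um (two voxels across
the neck) and dt = 0.025 ms, which resolves the sub-0.5 ms peak.

## What the synthetic geometries do and do not show

All validation geometries are ideal cylinders, branches and spines with
analytic references.  They exercise every code path (voxelization with
joins, partial volumes, areas, ADI on irregular domains, hybrid coupling,
membrane feedback) but are smooth and mildly sized; real reconstructions
add sampling noise, near-touching branches, and extreme aspect ratios
where the mesh quality depends strongly on `dx` — conclusions about
accuracy transfer only where the voxel size resolves the local geometry
(see `suggest_dx`).  Two benchmark quantities are known to be sensitive to
implementation details at this level: the exact voxel count of a branch
join (depends on the join-smoothing rule) and the peak voxel concentration
at a 2-voxel-wide spine-neck mouth, which swings by tens of percent with
the neck's alignment to the grid in control experiments (single-spine
runs at several tilt angles); neither is a stable measure of the physics.

## Known limitations

* Fixed-step integration only; no variable-step path, no stochastic
  kinetics, no electrodiffusion, no extracellular domain.
* Single-threaded; the line decomposition would partition across threads
  but no scheduling is implemented.
* Soma outlines (2D contours) are not supported; somas are frusta like
  any other section.
* The junction distance estimate uses half the boundary segment's length
  as stated, even when `nseg` varies along the section.
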