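# Methods

`tenposim` simulates immunomagnetic sorting of extracellular vesicles (EVs)
on track-etched magnetic nanopore (TENPO) membranes: a polycarbonate filter
(5 µm backing) coated with a 200 nm NiFe film, pierced by millions of
cylindrical pores, placed in the vertical field of a permanent magnet.
EVs are labeled with 50 nm magnetic nanoparticles (MNPs); as the sample is
pumped through, labeled EVs are pulled onto magnetophoretic traps that form
at each pore's edge, while unlabeled or weakly labeled material passes
through.  The simulation couples three single-pore models — magnetostatics,
unit-cell Stokes flow, and overdamped particle tracking — and aggregates
them into device-level capture rates.

## Device model

Each pore owns a cylindrical unit cell of radius `R_cell = (π·n_A)^(−1/2)`
(`n_A` = pore areal density) carrying an equal share `Q = ɸ/N` of the total
volumetric flow ɸ through the `N = n_A·a` pores of a membrane of area `a`.
The mean in-pore velocity is `V_z = ɸ/(N·π(d/2)²)`.

The canonical pore densities scale as `n_A(d) = n_A(3 µm)·(3 µm/d)²`,
anchored to the reference 3 µm membrane (2.12×10⁶ cm⁻², 5.3×10⁶ pores on
2.5 cm²).  This keeps the open-area fraction (≈ 0.15), and therefore `V_z`
at fixed ɸ, identical across pore diameters, so a diameter scan isolates
geometry effects from velocity effects.  Any density can be set explicitly.

A single pore's hydraulic resistance is the orifice end correction plus the
channel term, `R = 3µ/r³ + 8µL/(πr⁴)` with `L` the film-plus-backing
thickness (5.2 µm); the numerical solver below reproduces it within a few
percent.  Fully blocked pores at fixed total flow redistribute their flux
evenly over the open ones (parallel resistors): per-open-pore flux and, by
linearity of Stokes drag, the maximal drag on an entering EV grow by
`n/(n−k)` when `k` of `n` pores clog.

## Magnetostatics

The film magnetizes along the vertical drive `B_ext = 0.4 T`.  A uniformly
perpendicular-magnetized *infinite* sheet produces zero field, so by
Babinet superposition the field of the pierced sheet is

    B(r) = B_ext ẑ − B_disk(r),

where `B_disk` is the full field of a uniformly magnetized disk filling the
pore.  `B_disk` is evaluated exactly as the field of the disk's equivalent
surface current (a 200 nm solenoid on the pore wall) by quadrature of
circular current loops (elliptic-integral closed form), with panels refined
geometrically toward the film faces so evaluation stays accurate within
nanometers of the rim.  The on-axis magnetized-cylinder closed form serves
as an independent oracle (agreement to 10⁻⁶ relative).  |B| on the membrane
surface peaks at the pore edge for every canonical diameter — the
magnetophoretic trap.

**Film magnetization.** A perpendicular thin film self-demagnetizes: with
intrinsic susceptibility χ the magnetization is `M = χ/(1+χ)·H`, bounded by
the applied `H` itself, so a 0.4 T drive cannot bring NiFe
(µ0·Ms ≈ 0.79 T) anywhere near material saturation.  The canonical model
uses the linear-film value with µr = 1.844 (the permeability that maps the
reference 341 kA/m drive onto the 0.79 T flux scale):
`µ0·M = (µr−1)/µr · B_ext ≈ 0.183 T`.  This demagnetization-consistent
value reproduces the observed capture-rate structure across pore diameters
and flow rates; the fully saturated film
(`MagneticEnvironment.saturated()`) is kept as an option and roughly
quadruples the near-rim force, which markedly over-captures weakly tagged
particles.

For tracking, `∇|B|²` is tabulated on a rim-refined nonuniform grid (2 nm
step within min(d, 0.6 µm) of the wall and film, coarser tiers elsewhere)
and interpolated linearly; direct evaluation remains available everywhere
and is used by the tests and the force diagnostics.

## Hydrodynamics

Two flow representations share one interface:

* **Numerical reference (default for tracking).**  Steady axisymmetric
  Stokes flow on a staggered (r, z) grid of the unit cell — uniform inflow
  above, uniform outflow below, zero-shear symmetry at `R_cell`, no-slip on
  the membrane/pore walls via a solid mask — assembled as one sparse
  saddle-point system and factorized directly (default 144×288 cells).
  Mass conservation holds to <1 %, the long-tube limit reproduces
  Poiseuille within 2 %, and the pressure drop matches the
  orifice-plus-channel resistance within a few percent.  Stokes linearity
  lets one factorization serve every flow rate of a geometry.

* **Semi-analytic composite (fast path).**  A stream function
  `Ψ = −(Q/2π)·S(ρ,z)` built from the oblate-spheroidal orifice-drainage
  solution above the membrane (normalized so the cell boundary is a
  streamline) and, inside the channel, the semicircular mouth profile
  blended into a parabolic profile with the slowest Stokes entrance
  eigenmode (decay length 0.22 pore radii), fore-aft symmetric.  Mass
  conservation is exact by construction; agreement with the reference
  solver is within 10 % of the peak speed at d = 3 µm.  Its known
  limitation: tangential speed above the membrane vanishes quadratically
  with wall distance instead of linearly, which lengthens near-wall
  residence — the reason tracking defaults to the numerical field.

* **Clogs.**  A spherical clog of radius `R_c` on the pore edge, diameter
  protruding into the lumen, is axisymmetrized as a flux-equivalent annular
  constriction: open radius `b(z) = √(c² − s(z)²)` with `s(z)` the sphere's
  cross-section radius, i.e. the full blocked area is spread around the
  wall.  Flux is conserved; the 800 nm clog on a 3 µm pore raises the peak
  in-pore speed by ≈19 %.  The true azimuthally localized geometry cannot
  be represented; its capture-side effect appears only through trajectories
  passing the constriction surface.

## Particle transport

An EV–MNP complex is one 200 nm sphere (volume of a 150 nm EV plus 15
50 nm MNPs) whose tagging level sets an effective relative permeability:
µ = 1.00089 with 15 MNPs bound, 1.00009 with one.  In the dilute limit the
magnetophoretic force is `F = V·χ·∇|B|²/(2µ0)` with `χ = µ−1`; intermediate
MNP counts interpolate χ linearly between the two anchors (an extension,
not a first-principles model).  With particle Reynolds and Stokes numbers
≪ 1, motion is overdamped:

    dx/dt = v_fluid(x) + F(x)/(6πηR).

Inertia, gravity/buoyancy, Brownian motion, and near-wall mobility
corrections are omitted.  Trajectories are integrated by an adaptive Heun
scheme (per-step error bound 1 nm, displacement capped at 20 % of the wall
distance), all 100 release points stepped together as a vectorized batch.
A particle is **captured** when its center reaches a solid surface within a
5 nm contact tolerance — the freeze-on-contact condition of point-particle
tracing.  Capture is *not* triggered at one particle radius from the wall:
that would count pure streamline interception (several percent of releases
pass within 100 nm of the rim even with χ = 0) and would contradict both
the zero weak-tag capture of wide pores and the near-zero geometric
interception expected for d ≥ 1 µm.  A particle **escapes** when it crosses
the channel exit; the stray field decays within ~d of the film, so nothing
can be captured farther downstream.

**Residence budget.**  Capture counts only within 10 advective transit
times (transit = 3 µm approach + pore length over `V_z`; ≈ 0.44 s at the
reference condition).  Slower trajectories — particles creeping along the
membrane for seconds while a piconewton-scale vertical force slowly sinks
them — end as `max-steps` and count as not captured, with a warning.
Beyond a few transits the neglected Brownian motion (rms displacement
≈ 2 µm per √s for a 200 nm sphere in water) would dominate any
deterministic outcome, and capture times in practice separate cleanly into
fast rim trapping (< 2 s) and membrane creep (> 3 s), so the factor 10 is
not a sensitive threshold.

## Release grid and the axisymmetric surrogate

Each run releases 100 complexes from a uniform 10×10 grid of side 2d,
centered on the pore axis, 3 µm above the membrane.  The physical cell of
a pore in a square lattice is a square; this package's cell is a cylinder.
A release point (x, y) is mapped to the cylindrical-cell radius

    ρ_eff = (2/√π) · max(|x|, |y|),

which sends each square streamtube (level set of the square-cell
coordinate max(|x|,|y|)) to the circle enclosing exactly the same inflow
flux, and preserves the local outside-flux fraction at every azimuth.  The
map collapses the 100 grid points onto 5 distinct radii with orbit sizes
4/12/20/28/36, so single-membrane capture fractions are quantized in steps
of at least 4 %.  This is the main fidelity limit of the axisymmetric
surrogate: azimuthal effects that split a release ring (corner- vs
edge-ward points of the outermost ring behave differently in a true square
cell) cannot be represented, and intermediate capture fractions such as a
12 % weak-tag rate at d = 1 µm fall between orbit levels — this package
yields 36 % there.  Multi-membrane passes re-release uncaptured particles
at uniform random (x, y) over the same square (seeded generator), which
breaks the quantization from the second membrane on.

## What the model reproduces, and what it does not

At ɸ = 2.5 mL/h, a = 2.5 cm²: strong-tag capture Rs = 100 % at d = 0.6 and
1 µm, falling to 64 % (3 µm) and 28 % (12 µm); weak-tag capture
Rw = 84 %/36 %/0 %/0 % over the same diameters, so background rejection
1−Rw plateaus at 100 % for d ≥ 3 µm and the strong/weak separation peaks at
d = 1 µm.  At d = 1 µm, Rs stays 100 % up to exactly 2.5 mL/h and falls
beyond; Rw reaches 0 at high flow.  Stacked 3 µm membranes recover strong
yield (64→85→95→100 %) with shrinking marginal gains while weak capture
stays 0.  A 400 nm rim clog changes nothing; an 800 nm clog adds weak-tag
capture at unchanged strong-tag yield.  One-of-nine pore occlusion raises
the open-pore drag by the parallel-resistor bound 12.5 %.

The force-over-drag diagnostic 100 nm above the pore edge gives log10
ratios near 0 (15 MNPs) and −1 (1 MNP) — the two tagging levels are one
decade apart, but the absolute values are far below the three/two orders
sometimes quoted for such devices.  Those larger figures are not
self-consistent with zero weak-tag capture at wide pores: a weak-tag force
a hundredfold above drag at 100 nm from the edge would sweep every
near-wall particle into the trap.  The capture rates, not the probe-point
ratio, are the observable this package is calibrated against.

## Numerical choices

* Stokes solver 144×288 cells (validation suite also runs 48–96 wide
  grids); direct sparse LU with row equilibration; componentwise backward
  error < 10⁻⁸ enforced.
* Magnetic table: 2 nm fine step near the rim, sub-nm node offset keeps
  nodes off the virtual disk faces; gradients by second-order nonuniform
  differencing of |B|² on the grid.
* Integrator: Heun with per-particle adaptive dt, error bound 1 nm/step;
  outcomes are invariant for ≥ 98/100 canonical releases under a 10×
  tolerance refinement.
* Determinism: capture rates involve no randomness; membrane stacking uses
  one `numpy` generator seeded per run; result CSVs are byte-identical for
  identical seed and configuration.
* Degenerate inputs: zero flow gives zero velocity everywhere (capture
  fractions are then meaningless and the residence budget is infinite);
  clogs must not occlude the full pore; all-pore occlusion is rejected.

## Limitations

Axisymmetric surrogate (no azimuthal structure, quantized single-membrane
fractions); no Brownian motion, EV size/labeling heterogeneity, deformable
or accumulating clogs, particle–particle or magnetic dipole–dipole
interactions; near-wall hydrodynamic mobility corrections omitted; the
film's magnetization state is reduced to one effective uniform value; pore
placement is ideal (no overlapping double-tracks).  Real devices add
surface chemistry, polydispersity and labeling-distribution effects that
this geometric/physical model does not attempt.
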