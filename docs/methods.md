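# Methods

## The model

The system is a three-component slab: a polydimethylsiloxane (PDMS)
layer between two aqueous phases, loaded with one organic solute
species, bounded in x by rigid walls and periodic in y and z.  The
potential energy is the conventional sum of harmonic bond stretches,
harmonic angle bends, OPLS cosine-series dihedrals, and nonbonded 12-6
Lennard-Jones plus Coulomb interactions, with 1-2/1-3 neighbours
excluded and 1-4 neighbours scaled (default 0.5, the OPLS convention).
Harmonic terms use the LAMMPS-style convention `E = k (x − x0)²`; a
`half_harmonic` flag switches to the `½k` convention.

**PDMS** is united-atom: Si, backbone O, and CH₃ sites.  All fifteen
12-6 pair combinations among these are driven by an explicit pair table
(the tabulated cross pairs deliberately do not follow Lorentz–Berthelot
mixing and override it).  The CH₃ diameter, 3.86 Å, is the parent
model's 3.7298 Å enlarged by 3.49%; this correction compensates a
liquid-density overestimate of the unmodified parameter set and is taken
as given, not re-derived (`apply_ch3_sigma_modification` reproduces the
arithmetic).  PDMS partial charges and bonded constants are not part of
the tabulated set; the package ships physically reasonable siloxane
defaults (inner Si +0.30 e, terminal Si +0.15 e, O −0.30 e, CH₃ neutral;
soft Si–O–Si bending, a small backbone torsion barrier).  Every
partition, solubility and composition quantity computed downstream is
arithmetic over counts and volumes and does not depend on these
defaults.

**Water** is rigid SPC (O–H 1.0 Å, H–O–H 109.47°), held by SHAKE
distance constraints including the fictitious H–H distance
2·sin(θ/2) = 1.6329809 Å.

**Organics** are all-atom with OPLS-style types (aromatic C/H, hydroxyl
O/H, ether O, sp³ C/H, Cl); hydroxyl hydrogens are LJ-inactive.  The
water–organic cross ε carries a factor 1.20 — a correction fitted on the
water–phenol pair against aqueous diffusion data and, by default,
extended to all organic species (`apply_water_organic_scaling` can
restrict it to a subset).

**Electrostatics.**  Long-range mesh solvers are engine-scale machinery
with no bearing on any quantity this package reports, so electrostatics
uses short-range closures with a 12 Å cutoff: damped-shifted-force
(Fennell–Gezelter; energy and force both continuous at the cutoff,
default damping α = 0.2 Å⁻¹) or reaction-field (dielectric 78.5).  Both
reduce to direct Coulomb at short range.  LJ truncation is
energy-shifted by default; a shifted-force option exists and is what the
energy-conservation checks use, since a force discontinuity at the
cutoff is the dominant NVE drift source at desk scale.

**Walls** are planar, purely repulsive WCA-type potentials in the
x-distance, flagged to act on PDMS species only, so water and organics
permeate freely.  A single-layer FCC(100) patch of frozen decorative
sites marks each wall; the wall force itself is carried by the plane
(the patch's lattice constant, 3.92 Å, is configurable and its atom
count is geometry-dependent and only reported, never asserted).

## Dynamics

Velocity Verlet at 1 fs.  Temperature control is a global Nosé–Hoover
chain of length 3 (coupling time 100 fs), with a Langevin thermostat as
the fallback for very small systems where the deterministic chain
equilibrates poorly.  Pressure control is a first-order Berendsen-style
volume relaxation (coupling 1000 fs, compressibility 4.5×10⁻⁵ atm⁻¹,
per-step scale clamped to ±5%) acting on the periodic axes only — for
bulk annealing boxes all three, for slabs never the walled x axis.  This
volume relaxation does not generate a rigorous NPT distribution; it is
used solely to drive small boxes to their equilibrium density, which is
all any reported quantity asks of it.  SHAKE runs as a batched
per-molecule Newton solve (each rigid water is an independent
3-constraint cluster, so the 3×3 linearized systems are solved exactly
each iteration, converging to the 10⁻⁸ relative tolerance in a few
iterations); RATTLE projects the velocities afterwards.  Initial
velocities are Maxwell–Boltzmann draws with the net momentum zeroed;
trajectories never wrap coordinates, so recorded frames are continuous
in time and directly usable for MSD analysis.

The annealing protocol heats to 408.15 K and cools to 298.15 K in 10 K
steps with a fixed dwell per level, reporting the mean density and
potential energy over the kept tail of each dwell.  A steepest-descent
minimizer with a 0.2 Å displacement cap (constraint-projected every
move) takes packed initial configurations off their worst overlaps
before dynamics.

## Analysis

Molecules are located along x by the site nearest their center of mass
(ties to the lowest site index).  Density profiles use half-open 1.5 Å
bins anchored at the box lower edge.  Interfaces are, by default, where
the polymer profile crosses 50% of its plateau mean, linearly
interpolated between bin centers; fixed nominal positions can be
supplied instead.  Phase classification assigns a molecule to the
polymer phase on the closed interval [x_left+3 Å, x_right−3 Å], to the
aqueous phase outside [x_left−3 Å, x_right+3 Å], and excludes the 3 Å
interfacial margins from both — interfacially adsorbed molecules bias
neither concentration.  Concentrations and log P use the nominal
margin-free geometric volumes (28 Å × cross-section for the slab,
2 × 48 Å × cross-section for water in the reference geometry); the
margin-excluded volumes are also available.  log P uncertainties
propagate the block-averaged SEMs of the two phase counts to first
order: σ_logP = sqrt((σ_p/N_p)² + (σ_w/N_w)²)/ln 10.  The running-log-P
convergence check declares a plateau when a line fitted to the last 20%
of the series moves less than 0.05 log units across that window.

MSD uses multiple time origins over molecule centers of mass and
requires unwrapped coordinates; D = slope/(2n) with the slope and its
standard error from least squares over a configurable window (default:
skip the first 10% of lags).  Long lags of a finite trajectory are
noisy — parameter-recovery checks fit the well-sampled first half.

## Synthetic data: what it emulates and what it does not

The partition-scenario generator reproduces the *statistical structure*
of a slab trajectory: a polymer marker profile with sharp or smeared
edges, and mobile molecules placed per frame inside the phase interiors
according to prescribed occupancies — exactly (static mode) or through a
per-molecule two-state Markov jump process whose stationary split and
relaxation time are prescribed (the simplest process with the saturating
relaxation shape seen in partitioning runs).  The Brownian generator
draws Gaussian displacements with variance 2 D dt per axis.  Passing
round-trip tests therefore certifies the *analysis chain* — binning,
interface detection, exclusion margins, counting, unit conversions, fit
windows — not the force field or the sampling quality of real dynamics;
the engine-level checks (drift, thermostat, constraint, density-sign)
cover those separately, and nothing at desk scale certifies 65–100 ns
equilibration of a full-size system.

The Widom/counting cross-check uses two frozen LJ baths with ideal-gas
structure (uncorrelated uniform configurations).  The counting route is
an independence-sampling Metropolis walk over the joint (bath frame,
solute position) space; the insertion route Boltzmann-averages ghost
insertions over the same frames, with the ghost feeling both baths just
as the real solute does.  Both routes therefore estimate the same ratio
of configuration integrals and must agree within statistics — a genuine
dual-route check with no shared estimator code.  Ideal-gas bath
structure is chosen deliberately: it makes a third, closed-form check
available (μ_ex = −kT·N·ln(1 − ∫(1−e^(−βu))dV/V)), which the test suite
exercises through the second-virial integral.

## Problem sizes and defaults

The package's standard test problems are chosen to be the smallest that
still exercise the physics: a 125-site LJ fluid for energy conservation
(10⁴ steps at 1 fs), 32 SPC waters for thermostat and constraint checks
(~3 ps), 10 n=1 oligomers for the annealing density sign test (two
levels, 408.15 and 298.15 K, ~12 ps dwell after ~8 ps pre-equilibration),
150 walkers × 400 frames for diffusion recovery, and 2×10⁴ samples per
route for the partition cross-check.  Loadings follow the aqueous
solubility limits (mol %, floor of n_water·s/(100−s)); the reference
counts 75 n=1 + 14 n=2 give the 80:20-by-weight blend.  The 128 Å
reference box is decomposed as 2 Å wall margin + 48 Å water + 28 Å PDMS
+ 48 Å water + 2 Å margin; the annealing-stage geometry replaces the
water with 10 Å vacuum layers (48 Å total).  All widths are
configurable.

## Numerical choices

* Bin origin at the box lower edge; half-open bins; boundary ties go to
  the polymer side — both documented so edge assignment is reproducible.
* Pair singularities (r < 10⁻⁶ Å between interacting sites) raise an
  error rather than returning infinities.
* Dihedral forces use the exact analytic gradient of the cosine series
  (validated against central differences to 10⁻⁹ relative); collinear
  backbone geometries are guarded by clamping the normal-vector norms.
* Packing is random insertion with uniform random rotations, a
  close-packing feasibility bound checked up front, and a periodic-image
  aware KD-tree overlap test; deterministic under a fixed seed.
* All generators, the builder, the integrator and the CLI take a single
  seed; identical seed + config reproduces results bit for bit.

## Known limitations

* Aromatic rings carry no improper torsions; planarity is maintained by
  the ring bond/angle/dihedral network, which is adequate for packing
  and short runs but would let rings pucker slightly in long hot runs.
* The bulk PDMS density equilibrates below the experimental
  0.825 g/cm³ with the shipped default charges and bonded terms at the
  tiny box sizes used here; the annealing check is a *sign* test
  (cold denser than hot), not a density benchmark.
* Nonbonded evaluation is an O(N²) vectorized pair sweep — ample for
  desk-scale boxes (≲10³ sites), unsuitable for the full 2×10⁴-site
  reference system, whose construction (but not integration) is
  supported.
* The volume-relaxation barostat does not sample rigorous NPT
  fluctuations; ensemble-sensitive observables (e.g. compressibility
  from volume variance) should not be computed from it.
* LAMMPS data files preserve numeric bond/angle/dihedral type ids, not
  the package's type names (the format has no place for them); kind
  names survive via Masses-section comments.
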