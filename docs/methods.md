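# Methods

This note records the model, the numerical choices, and what the test
suite does and does not demonstrate.

## Model and units

All quantities use the "real" convention: Å, fs, kcal/mol, g/mol, K.
kB = 0.0019872041 kcal/mol/K, so kT = 0.6160 kcal/mol at the default
310 K; energies specified "in kT" are converted at the configured
temperature (Es = 6 kT → 3.696 kcal/mol).  Beads have mass 100 g/mol by
default.

Chains are strictly linear: consecutive beads share a harmonic bond
(Kb = 3 kcal/mol/Å², R0 = 10 Å) and consecutive triplets a cosine bending
term E = κ(1 − cos θ) with κ = 2 kcal/mol, where θ is the deviation from
collinearity — a straight chain costs nothing, matching the intended
"flexibility penalty" reading of the cosine angle style.

Non-specific cohesion is a Lennard-Jones well of depth Ens between all
bead pairs except directly bonded ones (backbone 1–2 neighbors and
currently bonded sticker pairs; 1–3 and 1–4 interact at full strength,
the `0 1 1` exclusion convention).  The LJ is truncated at Rmax = 2.5 σ
**without** an energy shift, matching the default behavior of the
`lj/cut` pair style this force field is meant to interoperate with; the
price is an energy jump of ≈ 0.016 Ens whenever a pair crosses the
cutoff, which caps total-energy conservation in long undamped runs at
roughly the 0.4% level regardless of timestep.  A pair of currently
unbonded complementary stickers inside Rcut still feels LJ; the exclusion
applies only while the bond exists.

Specific bonds use the shifted harmonic well
E = Es/(R0ₛ − Rcut)² [(R − R0ₛ)² − (Rcut − R0ₛ)²] for R < Rcut and zero
beyond, with R0ₛ = 1.122 σ = 11.22 Å and Rcut = R0ₛ + 1.5 Å.  The well
depth at R0ₛ is −Es and the energy vanishes continuously at Rcut, so bond
creation and deletion at the cutoff injects no energy.

## Integrator

Underdamped Langevin dynamics is integrated with a BAOAB splitting:
half kick with the conservative forces, half drift, an exact
Ornstein–Uhlenbeck velocity refresh (v ← c₁v + c₂ξ with
c₁ = exp(−dt/t_damp), c₂² = (1 − c₁²)·kT·ftm2v/m), half drift, half kick.
This was chosen over injecting friction and noise into the force array
inside a plain velocity-Verlet step because (a) with the thermostat off it
reduces *exactly* to velocity Verlet, giving a clean NVE limit for
integrator validation; (b) no noise state survives a step boundary, so a
run split into chunks — or through a restart file — is bit-identical to an
uninterrupted one; and (c) the free-particle observables used for
validation are exact: stationary kinetic energy (3/2) kT per bead and
D = kT·t_damp/m up to O(dt) corrections.  The scheme is validated
statistically (equipartition, diffusion, Boltzmann bond statistics), not
by bit-matching any particular engine.

Default dt = 15 fs; t_damp = 500 fs; the instability guard aborts when any
bead moves more than a quarter box in one step.  Measured with the smooth
force-field terms (LJ off), NVE drift at dt = 15 fs is ~2×10⁻⁴ over 10⁴
steps and grows monotonically through dt = 45 fs.

## Stochastic bond engine

Once every `bond_attempt_every` = 20 steps, after the position update:

1. **Break pass** — every bonded sticker pair with minimum-image
   R ≥ Rcut breaks with probability p_off.
2. **Create pass** — candidate pairs (complementary types, both unpaired,
   R ≤ Rcut) are collected, shuffled uniformly (Fisher–Yates on a
   dedicated stream), and visited in that order; each is accepted with
   probability p_on if both members are still unpaired.  Valency 1 is
   therefore strict by construction, and a sticker facing several free
   partners picks uniformly among them.

Break runs before create within one attempt so that a pair that breaks
and instantly re-forms appears as two logged events rather than being
silently masked.  p_on/p_off are per candidate pair per attempt step.  The
thermostat and the bond engine consume two independent PCG32 streams
(seeded separately, serialized into restart files), so bond statistics are
reproducible independently of the force noise.  Both streams are
implemented in the package rather than taken from a library so that their
state can be saved and restored exactly and results are stable across
platforms.

## Setup: packing and file formats

The packer places each chain as a self-avoiding random walk with fixed
bond length (default 10 Å): uniformly random start, uniformly random step
directions, rejection when a candidate bead comes within `min_separation`
(default σ = 10 Å) of any bead of another chain, or of a non-neighbor bead
of its own chain (the 1–3 bound is relaxed to 0.8 σ so moderate bending
angles remain reachable); a bounded number of retries precedes a
density-too-high error.  A coarse sphere-packing bound rejects plainly
infeasible requests up front.  Packing is seed-reproducible bit for bit.

Configurations round-trip through a LAMMPS-style "molecular" data file
(Masses/Coeffs/Atoms/Bonds/Angles/Velocities; atom roles ride in Masses
comments, active sticker bonds are bond type 2, p_on/p_off in the title
line).  Restart files are a versioned plain-text format storing positions,
images, velocities, the pairing table, the step counter and the RNG
streams with 17 significant digits, so a resumed run continues exactly.

## Validation experiments

**Two-particle detailed balance.**  Two complementary stickers diffuse in
an elongated periodic box; the bond state sampled at every attempt step
gives a 0/1 series from which the stationary probabilities, per-frame
transition rates and K_eq = π_U/π_B are estimated with the pair-count
estimators (π_U = N_U/(N_U+N_B), N_U = N_UU + N_UB, …).  Because
transitions alternate, |N_UB − N_BU| ≤ 1 exactly and the flux ratio
(π_U P_U→B)/(π_B P_B→U) = N_UB/N_BU is 1 up to one count.

The default box is 150 × 15 × 15 Å.  The cross-section accelerates
encounters (pseudo-1D search); the length was set by the estimator
statistics: unbound episodes end by diffusive return to the partner, whose
duration distribution is heavy-tailed up to the box recurrence time
(∝ L²/D), and a 300 Å box makes ln K_eq fluctuate by ~0.3 per 10⁶ frames
at Es = 7 kT.  Box volume enters only the K_eq *prefactor*; the Es-scaling
is volume-independent (verified against a Monte Carlo Boltzmann-integral
oracle in both boxes).

A subtlety worth recording: the exact Boltzmann expectation for this well
is ln K_eq = −Es/kT + ½ ln(Es/kT) + const — the thermal width of the
bound well shrinks as 1/√Es — so the measured slope of ln K_eq against
Es/kT is −1 + 1/(2 Es/kT) ≈ −0.88 over Es = 2–7 kT, not exactly −1.  At
the statistical power of a ~10⁶-frame experiment the fit cannot
distinguish the two (R² ≥ 0.99 either way); with better statistics the
deviation is resolved.  The acceptance test asserts the idealized −1 and
is expected to fail that single sub-assertion; the package reports the
measured slope with its standard error.

**Damping/diffusion scan.**  Free, non-interacting beads are simulated at
six damping times (100–4000 fs, dt = 10 fs); D comes from an
origin-averaged MSD with log-spaced lags fitted over lags > 10 t_damp
(past the ballistic regime) via MSD = 6 D t.  D matches kT·t_damp/m
within a few percent and log D vs log t_damp has unit slope: damping acts
as an inverse solvent viscosity, a purely kinetic knob.

**Phase titration.**  Each Es point restarts from the same preformed
cluster, runs with independent seeded streams, and time-averages
normalized ACO, saturation, and dissociation counts after discarding the
first 10% of samples; the threshold is the interpolated Es at which
normalized ACO crosses 0.5, an operationalization of the switch-like
transition.  The preformed cluster is built by packing the chains into a
compact central region (~2500 Å³ per bead) and annealing briefly at
Es = 8 kT.  Anneal and titration default to t_damp = 2000 fs: diffusion
is four times faster than at 500 fs, so the bond network reaches a steady
state in far fewer steps, while equilibrium observables (energies,
saturation, ACO) are damping-independent.

## Problem sizes in the test suite

The suite runs desk-scale versions of each experiment: the
detailed-balance scan uses 2×10⁶ frames per Es at six Es values; the
diffusion scan 100 beads × 2×10⁵ steps per damping value; the clustering
stand-in 40 chains (2 000 beads) in a density-matched box with a
4×10⁴-step anneal and 2.4×10⁴ steps per titration point.  At these sizes
the 40-chain system plateaus at a lower sticker saturation (~0.45) than a
400-chain system run two orders of magnitude longer would, so the suite
asserts the qualitative structure — saturation plateaus in time and is
monotone in Es, ACO titration is sigmoidal between 1/N and 1 — rather
than any particular plateau value.

## What the generator does and does not emulate

The built-in packer and the standard two-component template (50-bead
chains, 10 uniformly spaced stickers, heterotypic A–B binding) reproduce
the geometry and stoichiometry of the canonical two-component condensate
system, and the simulations regenerate every experiment from first
principles — no external data enters.  Real disordered proteins differ in
ways the model deliberately omits: sequence heterogeneity beyond the
block pattern, electrostatics, hydrodynamic interactions, and solvent
structure.  Passing tests therefore demonstrate the statistical mechanics
of the valency-limited sticker-spacer model, not agreement with any
specific protein system.

## Known limitations

- Single-process engine; no spatial domain decomposition.  Practical up
  to ~10⁴ beads at dense-cluster conditions.
- The sticker candidate search is O(S²) in the sticker count per attempt
  step; fine for S ≲ 10³.
- Truncated-unshifted LJ bounds NVE conservation (see above); with the
  thermostat on this is immaterial.
- No enhanced sampling (metadynamics-style biasing is out of scope), so
  deeply arrested states are reachable only by direct simulation.
- Instantaneous temperature in the thermo table uses 3N degrees of
  freedom without constraint or drift corrections.
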