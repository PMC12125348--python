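# Methods

Units package-wide: nm, ps (user-facing times in ns), kJ/mol, amu,
elementary charges. k_B T at 300 K = 2.494 kJ/mol.

## Monomer models

All species share a planar hexagon: a central core bead and six
shielding beads at circumradius 0.47 nm, bonded with k = 20,000
kJ mol⁻¹ nm⁻² at r₀ = 0.47 nm between nearest neighbours (core–vertex
and adjacent vertex–vertex — both distances equal 0.47 nm in a regular
hexagon of that circumradius) and k = 15,000 at r₀ = 0.94 nm across the
three diagonals. Non-bonded interactions within a molecule are excluded;
the molecule is held together entirely by its bonded terms.

A consequence worth knowing: because every bond lies in the hexagon
plane, out-of-plane bending has no linear stiffness — bond lengths
change only quadratically with transverse displacement, so the bending
energy is quartic. At 300 K the core wobbles ~0.05 nm along the normal.
This softness is part of the model (the diagonals keep the ring planar
only on average) and is included in the free-energy oracle (below).

Species parameters:

| species | beads | core ε (kJ/mol) | extras |
|---|---|---|---|
| M, M^R | 7 | 45 | — |
| M_coop, M_coop^R | 9 | 20 | ±1.4 e dipole beads on the axis |
| C | 8 | 45 (self and cross) | cap bead on the axis, ε = 0.2 with everything |

All Lennard-Jones terms use σ = 0.47 nm, truncated and
potential-shifted at 1.1 nm; the repulsive references (`^R`) truncate
and shift at the minimum 2^{1/6}σ (WCA) and zero the charges. Shield
beads interact purely repulsively (WCA) with all non-charge beads; the
shield repulsion strength is not uniquely determined by the model
description, and is set to ε = 45 kJ/mol (the core scale), configurable
via `build_interaction_table(shield_eps=...)`.

The M_coop dipole: two charge beads of mass one third of the regular
bead mass, each held at 0.14 nm from the core by a distance constraint,
kept collinear by a harmonic angle (charge–core–charge, k = 1500
kJ/mol, θ₀ = 180°). The 0.28 nm charge–charge separation is then an
emergent invariant (monitored in tests to 1%). Charge beads carry no
excluded volume and interact only with other dipoles' charges, through
a truncated-shifted Coulomb term with **relative dielectric ε_r = 15**
(`InteractionTable.epsilon_r`). The dielectric is a deliberate choice:
with unscreened charges the stacked-dipole energy (~−400 kJ/mol) would
dwarf the LJ scale and freeze the dynamics, whereas ε_r = 15 — the
implicit-solvent convention of the CG lineage these models belong to —
puts it at ~−26 kJ/mol, the scale at which an ε = 20 core reproduces the
coordination statistics of the ε = 45 model.

The regular bead mass is nowhere fixed by the model; the default is
72 amu (a common CG bead mass) and every transport quantity scales with
it (D ∝ 1/m for free beads).

## Engine

Implicit-solvent Langevin dynamics, cubic periodic box, minimum-image
convention. Positions are kept unwrapped (molecules stay whole;
diffusion is directly measurable); only pair distances are wrapped.

**Integrator.** BAOAB splitting (half-kick, half-drift,
Ornstein–Uhlenbeck velocity update, half-drift, half-kick) with
per-bead friction γ_i = m_i/τ, τ = 0.1 ps, and exactly matched noise,
in the spirit of GROMACS' `sd` integrator but not numerically identical
to it. BAOAB was chosen because its configurational marginal is
near-exact at finite time step (verified against the dimer free-energy
oracle; an impulse-leapfrog variant left O(1 kJ/mol) sampling bias at
20 fs). With friction and noise disabled it reduces to velocity Verlet.

* Default time step 20 fs. Dipolar systems default to 10 fs: the
  dipole bending mode (k = 1500 kJ/mol on beads of mass 24 with the
  72 amu default) sits at ω·dt ≈ 2.06 for 20 fs — past the Verlet
  stability boundary — and heats catastrophically; at 10 fs its
  statistics are correct.
* Kinetic temperature is reported from the post-O point of the cycle,
  where the velocity marginal is unbiased; full-step velocities read a
  few percent cold on the stiff ring bonds. NVE (validation) runs keep
  the conventional full-step estimate. Degrees of freedom: 3N minus one
  per distance constraint.
* Constraints (the core–charge links) use iterative SHAKE on positions
  (tolerance 10⁻⁶ nm) with RATTLE velocity projections after the O
  step, after the constrained drift, and after the closing kick.
* Neighbour search: a Verlet pair list built from all pairs with a
  0.2 nm skin, rebuilt when any bead has moved half the skin. At the
  system sizes this package simulates (≤ a few hundred molecules) the
  O(N²) build is negligible, and the pair list is by construction
  identical to the all-pairs reference.
* Energy-conservation validation runs use dt = 5 fs; at 20 fs the
  stiff-bond shadow-energy drift is visible in NVE (the Langevin
  thermostat dissipates it in production).
* Blow-up guard: any per-step displacement beyond 0.25 nm raises;
  interacting beads closer than 0.08 nm raise an overlap error naming
  the pair.
* Determinism: per-frame chunk seeds derive from (seed, absolute frame
  index), so identical seeds give bit-identical trajectories and a
  restart from a stored final state continues the original run exactly.
* Fresh random packings are relaxed by an adaptive steepest-descent
  minimiser before dynamics.

## Aggregation analysis

Bond rule with hysteresis: an unbound core pair binds when its
minimum-image distance drops below r_b = 0.6 nm; a bound pair unbinds
only beyond r_u = 0.9 nm; between the cutoffs the previous state
persists. The first frame uses the binding criterion alone (a
conservative initialisation; transitions are defined only between
consecutive frames). Assemblies are connected components, labelled by
their lowest member index (deterministic under relabelling). C monomers
are excluded before partitioning: an M bound only to a C is free with
stacking order φ = 0.

Size histograms use binary ranges {1},{2},{3–4},{5–8},…; per-frame
assembly-count fractions are averaged over the window and reported in
percent (so sparse frames are not over-weighted).

## Transition-network analytics

Transitions are counted per monomer: each monomer contributes one
(size_t → size_{t+lag}) event per usable frame pair, so the total count
is n_monomers × (n_frames − lag). Counts are summed into binary
size-ranges *before* row normalisation, keeping range-level matrices
row-stochastic. Rows with fewer than 500 raw counts (configurable) are
masked — replaced by self-transition so matrix powers stay stochastic,
and flagged in every derived quantity — mirroring the poor statistics
of rare large assemblies. Matrices are never symmetrised; detailed
balance is a property to test, not to enforce.

Longer lags come from matrix powers (valid for a Markovian series; the
Chapman–Kolmogorov test on planted chains is the module's central
oracle). Molecular traffic counts bond formation/rupture events by
default; a `mode="states"` flag counts per-monomer state changes
instead, since the two conventions differ for multi-bond events.
Resilience follows the perturbed/unperturbed ratio of
P_poly/P_depoly per size-range; zero denominators yield masked values
(NaN plus a mask bit), never infinities.

## LENS and event classification

LENS is computed over self-assembling monomer cores with a 0.7 nm
neighbourhood at the 0.3 ns sampling step; the value is the symmetric
set difference normalised by the summed neighbour counts, defined as 0
for empty→empty. Because the cutoff lies between r_b and r_u, bond
formation registers at the same frame pair while rupture can register a
frame or two earlier (the pair leaves the neighbourhood while
hysteresis still holds the bond).

The discrete nonzero values are classified mechanistically from the
bond-network context rather than from their numeric levels (which the
model does not pin): changed bonds at a frame pair are grouped by the
assembly they touch; a group spanning ≥4 distinct monomers is a
four-centre branching event, 3 monomers (or any junction of degree ≥3)
a branching event, an intra-assembly contact change is
bending/straightening, and a two-centre cross-assembly change is a
monomer exchange if the smaller fragment is a free monomer, otherwise
fibre polymerisation/depolymerisation (flagged multimeric). The
scripted scenario suite is the specification of this classifier: each
scenario carries its ground-truth labels and must be reproduced
exactly.

## Transport

MSD is time-origin- and particle-averaged over molecular centres of
mass (FFT algorithm), requiring unwrapped coordinates; D is the
least-squares slope over a configurable window (default the central
20–80% of the lag range; planted-recovery tests use short-lag windows
where time averaging is most efficient) divided by 6. Orientation ACFs
average u(t)·u(t+τ) over molecules and origins for the hexagon normal
or the dipole unit vector.

## Well-tempered metadynamics

Two monomers in a 3.5012 nm box (the stock concentration); the CV is
the minimum-image core–core distance. Kernels of width 0.1 nm and
initial height 0.1 kJ/mol are deposited every 10 ps with bias factor 5;
the bias is accumulated on a 700-point distance grid and its gradient
interpolated every step. A harmonic wall at 1.6 nm (k = 500) keeps the
pair out of the box corners; the wall force never enters the
free-energy estimate.

Two estimators are provided. The *bias* estimate
ΔF = −(γ/(γ−1))·V(r), time-averaged over late-run snapshots, has its
resolution limited by the kernel width (the narrow binding well is
visibly smoothed). The default *reweight* estimate histograms the CV
samples (recorded every 1 ps) with time-dependent weights
exp(β[V(s_t,t) − c(t)]), with c(t) from the standard well-tempered
offset formula; it converges to the unsmoothed profile and is the one
validated against the oracle. Profiles are re-zeroed at a reference
separation (default 1.4 nm; the box geometry leaves no truly
interaction-free distance, so the oracle uses the same convention). A
volume-correction toggle adds 2kT ln r, converting the CV free energy
into the orientation-averaged pair free energy.

ΔU(r) is the binned conditional mean of the unbiased potential energy
(within a bin the bias is constant, so reweighting factors cancel);
−TΔS = ΔF − ΔU pointwise by construction. Bins with too few samples are
masked. The estimator choice (final-bias conditional means) is
validated against the oracle's conditional Boltzmann averages.

The restrained-dipole variant pins one monomer's dipole along its plane
normal with two stiff 90° charge–core–vertex angle restraints,
emulating a fibre-tip monomer; its deeper binding well relative to the
free dimer is the cooperativity signature.

**Oracle.** The independent cross-check never touches the dynamics: by
the free-energy perturbation identity,
F(r) − F(∞) = −kT ln ⟨exp(−U_inter/kT)⟩₀, with the average taken over
the non-interacting pair ensemble — uniform orientations and
separation directions, independent dipole directions, and internal
conformations drawn from the isolated-molecule Boltzmann ensemble. The
internal ensemble is sampled by a vectorised single-bead Metropolis MC
on the bonded energy (the floppy out-of-plane modes contribute >1
kJ/mol to the pair free energy and must not be rigidified); the dipole
geometry is handled analytically (free rotor plus the harmonic-angle
distribution). Minimum-image distances use the same box as the
dynamics, so both routes share one convention. Agreement of the
reweighted metadynamics profile with this oracle over the attractive
well, at the sub-kJ/mol level, is the package's strongest end-to-end
check (engine forces, thermostat, constraints, bias machinery and
reweighting must all be right simultaneously).

## Synthetic fixtures

Planted Markov series evolve each monomer independently from a known
row-stochastic matrix (stationary initialisation) — a deliberate
simplification with no global size conservation, adequate for testing
the estimators but not a model of coupled assembly dynamics. Ideal
fibres stack monomers at the LJ-minimum spacing 2^{1/6}·0.47 nm with
head-to-tail dipoles. The scripted scenarios (binding, unbinding,
fission, fusion, bend/straighten, three- and four-centre branching,
hysteresis oscillation, ramped dimer break) encode frame-by-frame
coordinates with exact expected sizes, traffic and event labels, and
serialise to the standard trajectory container so analyses cannot
distinguish them from simulations.

What passing these tests shows — and does not. The fixtures validate
the bookkeeping and estimators exactly and the engine's statistical
mechanics at desk scale (tens of monomers, tens of ns, dimer free
energies). They do not reproduce large-system equilibrium observables
(equilibrium size distributions, traffic slopes, resilience curves of
2000-monomer systems over tens of microseconds), which remain outside
desk-scale compute; at desk scale those appear only as qualitative
trends (assembly onset, weaker cooperative dimerisation).

## Problem sizes used in the shipped checks

Chosen as the package's own desk-scale protocol: 500-bead ideal-gas
runs of 1 ns for thermostat/diffusion checks; 10-monomer, 15–25 ns
self-assembly runs; planted chains of 2–8×10⁵ samples; metadynamics
runs of 120–150 ns per seed (2–3 seeds) against oracles of 1–3×10⁵
Boltzmann samples per distance.

## Known limitations

* No pressure coupling, no long-range electrostatics (by design of the
  model), no bonded-type extensibility beyond the five species.
* O(N²) neighbour-list builds cap practical system sizes at a few
  thousand beads.
* Transport quantities depend on the configurable bead mass.
* The `sd`-style integrator is BAOAB, not GROMACS's exact update; only
  statistical properties, not trajectories, are comparable.
* Metadynamics supports a single distance CV between two monomers.
* The angle-mode statistics of the dipole are slightly cold at 10 fs
  (~1.8 vs 2.5 kJ/mol mean bending energy); dipolar free-energy
  comparisons at the 0.5 kJ/mol level should use 5 fs.
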