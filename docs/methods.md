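# Model and methods

## The physical model

A dialyzed dispersion is represented by its retentate only: a cubic
periodic box holding N_np rigid nanoparticles and small ions (Na⁺, Cl⁻,
H⁺, OH⁻), in osmotic equilibrium with an infinite permeate reservoir of
prescribed pH and NaCl concentration.  The membrane is implicit — the
reservoir coupling *is* the membrane.

Each nanoparticle is a rigid body: a repulsive core of effective diameter
d_np (default 1.42 nm = 4 ion diameters) carrying n_sites ionizable acid
sites (default 10, pKa 4.0) as massless point charges on the core surface
(site radius d_np/2 by default, configurable).  The sites occupy a single
spherical cap covering a fraction (1 − θ) of the surface; θ = 0 is
uniform coverage, θ = 0.9 confines the sites to 10% of the surface.
Within the cap the sites are spread approximately uniformly by minimizing
Σ_{i<j} 1/|r_i − r_j| (a Thomson-type objective) with projected-gradient
descent under the cap constraint; random initialization from a seed, a
fixed iteration budget of 10⁴ steps and a relative objective tolerance of
1e−10 make layouts deterministic per seed.  The cap half-angle follows
from the area fraction: cos t_cap = 1 − 2(1 − θ).

### Interactions

Units: energies in k_BT, lengths in nm.

- **Short range**: offset WCA (cut-and-shifted LJ, purely repulsive),
  ε = 1 k_BT, σ = d_ion = 0.355 nm, cutoff 2^(1/6) σ beyond the offset.
  Offsets encode effective sizes via the contact rule
  r_off = (d_i + d_j)/2 − σ: ion–ion 0, core–ion 0.5325 nm, core–core
  1.065 nm for the defaults.  The potential is infinite at r ≤ r_off
  (certain rejection).  Sites have no excluded volume of their own; only
  the core repels.  The core carries no charge; only sites and ions do.
- **Electrostatics**: full Coulomb, u = λ_B z_i z_j / r with
  λ_B = e²/(4π ε₀ ε_r k_B T) = 0.71 nm (ε_r 78.5, 298 K).  The periodic
  sum uses classical Ewald summation with conducting (tinfoil) boundary,
  splitting parameter and k-cutoff chosen from the standard exponential
  error estimates for a relative accuracy of 1e−3 (validated against the
  tabulated NaCl Madelung constant to ~1e−5).  Real-space cutoff is half
  the box edge; the structure factor is cached and updated incrementally
  per accepted move.

### Reservoir

Given target pH (activity convention, pH = −log10(γ± c_H/c°)) and salt
concentration, the permeate composition {H⁺, OH⁻, Na⁺, Cl⁻} follows from
electroneutrality (pH is set by excess HCl below 7, excess NaOH above)
and the water activity product K_w = 1e−14.  The mean activity
coefficient comes from the Davies equation,
log10 γ = −0.509 z² (√I/(1+√I) − 0.3 I), iterated to self-consistency
with the ionic strength; an `ideal` mode (γ = 1) exists for comparison
with ideal-gas theory.  The ion-pair exchange constants are
K_ij = γ±² c_i c_j / c°², and the acid move's composite variants use
K_A·K_NaCl/K_HCl (HA → A⁻ + Na⁺) and K_A/K_w (HA + OH⁻ → A⁻), so every
reaction is electroneutral and consistent with the same reservoir.

### Sampling

Configurational space is sampled by Metropolis Monte Carlo — single-ion
displacements and rigid nanoparticle displacements/rotations — which
targets the same canonical distribution as a thermostatted dynamics;
only equilibrium averages are reported, never trajectories.  Reaction
moves (three acid variants, four pair exchanges, picked uniformly,
direction ±1 with probability ½) use the reaction-ensemble acceptance
probability with exact integer species counts; a deletion whose reactant
is absent counts as an attempted, rejected move.  Every move conserves
the total charge exactly, so electroneutrality is an invariant, not a
constraint to monitor.

A cycle is `config_moves_per_cycle` configurational trials followed by
`reaction_moves_per_cycle` reaction trials (defaults 1000 + 250, a 4:1
configurational-to-reaction effort ratio that keeps both position and
composition relaxation comparable for these system sizes).  The displacement step is tuned toward 30–50%
acceptance during the equilibration fraction of the run (default the
first 30%) and frozen afterwards, since tuning during production would
break detailed balance.  A single seeded generator drives everything;
runs are bitwise reproducible per seed.

In `fixed_fraction` mode every site carries the constant charge
−α_fixed instead of titrating.  Because the total site charge must be
neutralized by an integer number of Na⁺ counterions, α_fixed is snapped
to the nearest value making α·n_sites·N_np an integer (a shift of at
most 0.5/(n_sites·N_np), e.g. 0.01 for 5 particles); the snapped value
is what the simulation reports.  `no_electrostatics` keeps only WCA;
`no_interactions` makes every ΔU zero, which reduces the stationary
distribution to the ideal Donnan + Henderson–Hasselbalch ensemble — the
engine's exactness oracle.

### Observables and errors

Recorded per observation interval: α, species counts, total and Coulomb
energy.  Concentrations use the full box volume (the operational
definition of the distribution ratio uses concentrations, not
activities or free-volume corrections).  Means and errors come from
block averaging with block-size doubling until the blocked SE changes by
less than 5% over two doublings; the implied autocorrelation time is
τ = (SE/SE_naive)²/2 sampling intervals.  The first 30% of each series is
discarded as equilibration (configurable); the visual-inspection
equilibration check of the original protocol is replaced by this
reproducible plateau criterion.

### Theory module

The ideal Donnan ratio solves D·I = I/D + c_A, giving
D₊ = [c_A + √(c_A² + 4I²)]/(2I), D₋ = 1/D₊, ΔpH = −log10 D₊,
ψ_Don = −(k_BT/e) ln D₊.  The coupled solver iterates
α = HH(pH_perm + ΔpH(α·c_acid)) with damping 0.5 (pure iteration can
oscillate near steep titration regions) to 1e−12 in α.  The permeate
ionic strength includes the H⁺/OH⁻ (strong acid/base) contributions by
default — this is what suppresses the Donnan effect at extreme pH even
at constant salt; a flag exposes the salt-only variant.

## Scale of the shipped experiments

The test suite and the acceptance script run deliberately reduced systems
chosen as this package's own desk-scale study design: 3–10 nanoparticles,
20–50 salt pairs, 200–500 cycles, rather than the ≥10 particles, ~250
pairs and 5000 cycles of a production study.  At this scale the ideal
limits are exact, the patchiness ordering of α and the titrating vs
fixed-charge equivalence are resolved well beyond 3σ, and the steric
Widom estimate reaches ~0.1% statistical error; the full multi-decade
titration curves (e.g. the ~4 pH-unit shift at α = 0.5 for θ = 0.9)
would require production-scale electrostatic runs and are represented by
these scaled-down ordering and oracle-equivalence checks instead.

A systematic effect visible at this reduced scale: in strongly coupled
small boxes (low salt, highly charged particles) the measured
concentration-ratio product D₊·D₋ exceeds 1 by (γ±^perm/γ±^ret)², because
the retentate's salt activity coefficient drops below the permeate's.
This is real electrolyte nonideality, resolved here only because the
scaled-down state points are more strongly coupled than a production
study's; the ideal reciprocity is therefore asserted at a
moderate-coupling state point (0.1 M salt, weak Donnan), where it holds
within sampling error.

## What the generated data does and does not show

All inputs are generated internally (site layouts, initial
configurations); there are no external datasets.  The model demonstrates
the interplay of Donnan, polyelectrolyte and steric effects in a
minimal, fully controlled setting.  It does **not** represent any real
protein: the particles are smaller, the sites closer together and purely
acidic, the buffer has no multivalent or titratable species, and the
solvent is a structureless dielectric.  Passing tests certify the
statistical mechanics of the model — ideal-limit exactness, detailed
balance, estimator calibration — not quantitative agreement with any
laboratory dialysis experiment.

## Numerical choices

- Ewald accuracy parameter p = 3.6 (truncation error ~2e−6, safely below
  the 1e−3 target); weight-2 half-space k-vector list; neutrality is
  asserted, no background correction.
- WCA evaluated with minimum image; box edges are validated against
  twice the largest cutoff.
- Energies are tracked incrementally and verified against from-scratch
  recomputation (the suite requires agreement within 1e−6 k_BT per
  particle after thousands of accepted moves; observed drift is ~1e−13).
- Acceptance exponentials clip ΔU to ±700 to avoid overflow; infinite
  ΔU short-circuits to rejection.
- Reservoir self-consistency iterations converge to 1e−12 relative in
  γ±; the Davies coefficients are A = 0.509, linear term 0.3 (25 °C) —
  at I ≤ 0.1 the reported observables are insensitive to this choice at
  the quoted precision.
- The mean site distance d_q is reported as the nearest-neighbour
  average (primary) and the all-pairs average (secondary); "average site
  distance" is ambiguous between the two conventions and depends on the
  assumed site radius, so d_q values are layout diagnostics, with only
  their ordering in θ regarded as characteristic.

## Known limitations

- Single patch per particle, acidic sites only, monovalent ions only,
  spherical cores; no basic residues, buffers, or multivalent ions.
- No dynamics: transport properties are out of scope by construction.
- Grand-canonical H⁺ statistics are poor above pH ≈ 4 in desk-scale
  boxes (the expected free-proton count is ≪ 1), so D_H carries large
  errors there; D_Na is the practical cation ratio, as in the underlying
  theory.
- The fixed-fraction mode's charge snapping makes its α differ from the
  titrating mean by up to 0.5/(n_sites·N_np).
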