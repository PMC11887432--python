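# patchtitrate

Charge regulation and Donnan partitioning of patchy nanoparticles under
dialysis, by reaction-ensemble + grand-canonical Monte Carlo with a
closed-form Donnan / Henderson–Hasselbalch reference theory.

## The problem

When a solution of charged macromolecules (proteins, colloidal
nanoparticles) is dialyzed against a buffer through a membrane permeable
only to small ions, the confined charges force an asymmetric ion
distribution between the two compartments — the Donnan effect.  For ion
*i* it is quantified by the distribution ratio

```
D_i = c_i^ret / c_i^perm ,        ΔpH = pH_ret − pH_perm = −log10 D_+
```

For monovalent ions modeled with identical potentials, all cation ratios
are equal and D₊·D₋ = 1 in the ideal limit.  The macromolecular charge is
itself pH-dependent through the acid–base equilibrium of the surface
groups: the degree of ionization α = N_A⁻/(N_A⁻ + N_HA) obeys the
Henderson–Hasselbalch relation α = 1/(1 + 10^(pKa − pH_ret)) — but at the
*retentate* pH, which the Donnan shift itself depends on.  On top of this
feedback loop, electrostatic repulsion between nearby ionized sites
(the polyelectrolyte effect) suppresses ionization further, and the more
so the more the sites are crowded into a surface patch.

`patchtitrate` implements a minimal particle-based model of this
situation: rigid spheres (effective diameter d_np = 1.42 nm) carrying
n = 10 weakly acidic sites (pKa = 4.0) on the surface, with a degree of
patchiness θ — the sites occupy a spherical cap covering a fraction
(1 − θ) of the surface.  Small ions (Na⁺, Cl⁻, H⁺, OH⁻; d_ion = 0.355 nm)
interact through an offset, purely repulsive WCA potential plus the full
Coulomb potential with Bjerrum length λ_B = 0.71 nm (water, 298 K),
evaluated by Ewald summation.  The box is coupled to a reservoir at fixed
pH and salt concentration through electroneutral virtual reactions
(acid-site titration moves and NaCl / HCl / NaOH / HOH pair exchanges)
accepted with the reaction-ensemble probability

```
P_acc = min{1, K^ξ · Π_i N_i!/(N_i + ξν_i)! · (V N_A c°)^(ξ ν̄) · e^(−βΔU)}
```

The closed-form ideal theory — D₊ = [c_A + √(c_A² + 4I²)]/(2I) coupled
self-consistently to Henderson–Hasselbalch — is provided as the analytic
reference the simulations are compared against.

## Worked example

Site layouts and mean nearest-neighbour site distances d_q (nm) at the
default 10 sites per particle:

```
$ patchtitrate placement --thetas 0,0.5,0.75,0.9 --seed 1
theta,d_q_nm,d_q_over_lB,d_allpairs_nm
0.00,0.7629,1.0745,1.0311
0.50,0.6240,0.8788,0.9895
0.75,0.4675,0.6584,0.8152
0.90,0.3073,0.4329,0.5521
```

Tightening the patch drives neighbouring sites from beyond the Bjerrum
length (d_q/λ_B ≈ 1.07 at uniform coverage) to well inside it (0.43 at
θ = 0.9), which is why patchy particles ionize less readily: each new
charge costs more than k_BT of repulsion against its neighbours.

The analytic HH+Donnan reference at volume fraction 0.0036 against a
0.1 M buffer:

```
$ patchtitrate theory --pH-range 3:7:5 --phi 0.0036 --c-salt 0.1
pH_perm,alpha,D_plus,delta_pH,pH_ret
3.0000,0.089460,1.017815,-0.007669,2.9923
4.0000,0.476335,1.099362,-0.041141,3.9589
5.0000,0.893350,1.193823,-0.076940,4.9231
6.0000,0.987984,1.216186,-0.085000,5.9150
7.0000,0.998783,1.218759,-0.085918,6.9141
```

α rises with pH while the growing particle charge pulls the retentate pH
below the permeate pH (ΔpH < 0 for anionic particles, saturating as
α → 1).

Steric-only partitioning (uncharged particles, volume fraction 0.1,
particle-to-ion size ratio 8), by Widom insertion:

```
$ patchtitrate steric --phi 0.1 --ratio 8 --seed 1
{"D_plus": 0.8559, "SE": 0.0012, "phi_np": 0.1, "size_ratio": 8.0}
```

Excluded volume alone depletes small ions by only ~14% even at this high
volume fraction — crowding is a minor correction next to the Donnan
effect, which reaches D₊ ≳ 100 under the same conditions when the
particles are fully charged.

A full simulation is driven by a TOML config
(`patchtitrate run --config run.toml --mode full`); see
`patchtitrate run --help` and the `[reservoir]`, `[particle]`, `[system]`,
`[schedule]` blocks documented in `docs/methods.md`.  Sweeps over pH, θ,
volume fraction or salt emit tidy CSV
(`patchtitrate sweep --config run.toml --axis pH --values 3,4,5,6`).

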