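"""Steric-only ion partitioning into uncharged nanoparticle dispersions.

With electrostatics off, the asymmetry of small-ion partitioning between
retentate and permeate comes purely from excluded volume.  Two independent
estimators are provided: Widom test-particle insertion (the distribution
ratio equals ``exp(-beta mu_ex) = <exp(-beta dU_insert)>`` against an ideal
permeate at matched conditions) and a charge-free grand-canonical run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from patchtitrate.energy import CORE, ION, EnergyModel, wca_energy_array
from patchtitrate.geometry import AVOGADRO_PER_NM3_MOLAR, BoxSpec, NanoparticleTemplate
from patchtitrate.mc_engine import MCSchedule, build_initial_state, run
from patchtitrate.reservoir import ReservoirSpec

__all__ = ["StericRunSpec", "model_for_diameters", "widom_D_plus", "gcmc_D_plus"]


def model_for_diameters(d_np: float, d_ion: float = 0.355) -> EnergyModel:
    """Energy model with WCA offsets for the given effective diameters.

    Contact distances are arithmetic means of the diameters:
    ``r_off(ij) = (d_i + d_j)/2 - sigma`` with ``sigma = d_ion``.
    """
    if d_np <= 0 or d_ion <= 0:
        raise ValueError("diameters must be positive")
    return EnergyModel(
        sigma=d_ion,
        offsets={
            frozenset((ION,)): 0.0,
            frozenset((ION, CORE)): (d_np + d_ion) / 2.0 - d_ion,
            frozenset((CORE,)): d_np - d_ion,
        },
    )


@dataclass(frozen=True)
class StericRunSpec:
    """Conditions of one steric-partitioning experiment."""

    phi_np: float = 0.1
    d_np: float = 2.84
    d_ion: float = 0.355
    n_np: int = 32
    n_insertions: int = 1000  # per stored configuration
    n_configs: int = 100
    equilibration_sweeps: int = 200
    decorrelation_sweeps: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi_np < 0.5:
            raise ValueError("phi_np must be in [0, 0.5)")
        if self.d_np <= 0 or self.d_ion <= 0:
            raise ValueError("diameters must be positive")

    @property
    def box(self) -> BoxSpec:
        if self.phi_np == 0.0:
            return BoxSpec(edge_length=10.0 * self.d_np)
        volume = self.n_np * (np.pi / 6.0) * self.d_np**3 / self.phi_np
        return BoxSpec(edge_length=volume ** (1.0 / 3.0))


def _equilibrate_cores(
    spec: StericRunSpec, model: EnergyModel, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Random insertion then WCA displacement sweeps; returns positions, step."""
    L = spec.box.edge_length
    r_off = model.offset(CORE, CORE)
    pos = np.empty((0, 3))
    attempts = 0
    while len(pos) < spec.n_np:
        r = rng.uniform(0.0, L, size=3)
        if len(pos):
            d = pos - r
            d -= L * np.round(d / L)
            if np.any(np.sum(d * d, axis=1) <= r_off**2):
                attempts += 1
                if attempts > 10_000_000:
                    raise RuntimeError("cannot place cores at this volume fraction")
                continue
        pos = np.vstack([pos, r])
    step = 0.5 * spec.d_np
    _sweeps(pos, L, model, rng, spec.equilibration_sweeps, step)
    return pos, step


def _core_energy(r: np.ndarray, pos: np.ndarray, L: float, model: EnergyModel, skip: int) -> float:
    d = np.delete(pos, skip, axis=0) - r
    d -= L * np.round(d / L)
    dist = np.sqrt(np.sum(d * d, axis=1))
    return float(np.sum(wca_energy_array(dist, model.offset(CORE, CORE), model)))


def _sweeps(
    pos: np.ndarray,
    L: float,
    model: EnergyModel,
    rng: np.random.Generator,
    n_sweeps: int,
    step: float,
) -> None:
    n = len(pos)
    for _ in range(n_sweeps):
        for _ in range(n):
            i = int(rng.integers(n))
            new = (pos[i] + step * rng.uniform(-0.5, 0.5, size=3)) % L
            u_new = _core_energy(new, pos, L, model, i)
            if not np.isfinite(u_new):
                continue
            u_old = _core_energy(pos[i], pos, L, model, i)
            dU = u_new - u_old
            if dU <= 0 or rng.random() < np.exp(-dU):
                pos[i] = new


def widom_D_plus(spec: StericRunSpec, model: EnergyModel | None = None) -> tuple[float, float]:
    """Widom-insertion estimate of the steric distribution ratio.

    Equilibrates neutral WCA cores at ``phi_np``, then Boltzmann-averages
    ``exp(-beta dU)`` over uniform trial ion insertions in decorrelated
    configurations.  Returns ``(D_plus, SE)`` with the SE over
    configurations.
    """
    model = model or model_for_diameters(spec.d_np, spec.d_ion)
    rng = np.random.default_rng(spec.seed)
    if spec.phi_np == 0.0:
        return 1.0, 0.0
    L = spec.box.edge_length
    pos, step = _equilibrate_cores(spec, model, rng)
    r_off = model.offset(ION, CORE)
    per_config = np.empty(spec.n_configs)
    for c in range(spec.n_configs):
        _sweeps(pos, L, model, rng, spec.decorrelation_sweeps, step)
        trial = rng.uniform(0.0, L, size=(spec.n_insertions, 3))
        d = trial[:, None, :] - pos[None, :, :]
        d -= L * np.round(d / L)
        dist = np.sqrt(np.sum(d * d, axis=-1))
        u = wca_energy_array(dist, r_off, model)
        u_tot = np.sum(np.where(np.isfinite(u), u, np.inf), axis=1)
        per_config[c] = np.mean(np.exp(-np.clip(u_tot, 0.0, 700.0)))
    D = float(np.mean(per_config))
    se = float(np.std(per_config, ddof=1) / np.sqrt(spec.n_configs))
    return D, se


def gcmc_D_plus(
    spec: StericRunSpec,
    c_salt: float = 0.1,
    n_cycles: int = 400,
    model: EnergyModel | None = None,
) -> tuple[float, float]:
    """Charge-free grand-canonical estimate of the steric distribution ratio.

    Runs NaCl pair exchanges against an ideal reservoir at ``c_salt`` with
    electrostatics off; ``D_plus = <c_Na_ret> / c_Na_perm``.
    """
    model = model or model_for_diameters(spec.d_np, spec.d_ion)
    template = NanoparticleTemplate.build(
        n_sites=1, theta=0.0, core_diameter=spec.d_np, charge_mode="neutral", seed=spec.seed
    )
    box = spec.box
    n_pairs = max(1, int(round(c_salt * AVOGADRO_PER_NM3_MOLAR * box.volume)))
    reservoir = ReservoirSpec(
        pH=7.0,
        c_salt=c_salt,
        conc={"H": 0.0, "OH": 0.0, "Na": c_salt, "Cl": c_salt},
        ionic_strength=c_salt,
        gamma_pm=1.0,
        constants={"NaCl": c_salt**2, "HCl": 1e-300, "NaOH": 1e-300, "HOH": 1e-300},
        activity_model="ideal",
    )
    state = build_initial_state(box, template, spec.n_np, n_pairs, spec.seed, model)
    schedule = MCSchedule(
        n_cycles=n_cycles,
        config_moves_per_cycle=2 * (spec.n_np + n_pairs),
        reaction_moves_per_cycle=max(50, n_pairs),
        seed=spec.seed,
        observe_every=1,
    )
    series = run(state, schedule, model, reservoir, mode="no_electrostatics")
    c = series.concentration("Na")
    return c.mean / c_salt, c.se / c_salt
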