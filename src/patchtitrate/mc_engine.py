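"""Grand-reaction Monte Carlo engine for the retentate ensemble.

Samples a dispersion of rigid patchy nanoparticles and small ions (Na+, Cl-,
H+, OH-) coupled to an ion reservoir at fixed pH and salt.  Three move
families act on a single mutable :class:`SystemState`:

- canonical configurational moves: single-ion displacements and rigid
  nanoparticle displacements / rotations (Metropolis);
- reaction-ensemble acid-base moves: the site identity HA <-> A- flips while
  an H+ is inserted/deleted (or, in composite variants, a Na+ is exchanged or
  an OH- consumed), accepted with the reaction-ensemble probability
  ``min{1, K^xi prod_i N_i!/(N_i+xi nu_i)! (V N_A c0)^(xi nubar) e^(-beta dU)}``;
- grand-canonical electroneutral ion-pair exchanges (NaCl, HCl, NaOH, HOH)
  with constants derived from the reservoir composition.

Every move conserves the total charge exactly, so the system stays neutral
by construction.  Configurational sampling by Metropolis MC targets the same
canonical distribution as a thermostatted dynamics would; only equilibrium
averages are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from patchtitrate.energy import CORE, ION, EnergyModel, Ewald, wca_energy_array
from patchtitrate.geometry import (
    AVOGADRO_PER_NM3_MOLAR,
    BoxSpec,
    NanoparticleTemplate,
    Pose,
    world_site_positions,
)
from patchtitrate.observables import ObservableSeries
from patchtitrate.reservoir import ReservoirSpec, composite_acid_constants

__all__ = [
    "SPECIES",
    "MCSchedule",
    "ReactionSpec",
    "SystemState",
    "build_initial_state",
    "run",
]

#: ion species codes and valencies
SPECIES = ("Na", "Cl", "H", "OH")
VALENCY = np.array([1.0, -1.0, 1.0, -1.0])
_CODE = {name: i for i, name in enumerate(SPECIES)}

MODES = ("full", "no_electrostatics", "no_interactions", "fixed_fraction")


class InitializationError(RuntimeError):
    """Could not build a non-overlapping initial configuration."""


@dataclass(frozen=True)
class ReactionSpec:
    """One virtual reaction: signed stoichiometry and equilibrium constant.

    ``stoichiometry`` maps species names (ion species plus the site states
    "HA"/"A") to signed integers; ``nu_bar`` is their sum, which sets the
    power of the ``V N_A c0`` volume factor in the acceptance rule.
    """

    name: str
    stoichiometry: dict
    K: float

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("equilibrium constant must be positive")

    @property
    def nu_bar(self) -> int:
        return sum(self.stoichiometry.values())


@dataclass
class MCSchedule:
    """Move schedule: cycle counts, step sizes, seeding, discard fraction."""

    n_cycles: int = 1000
    config_moves_per_cycle: int = 1000
    reaction_moves_per_cycle: int = 250
    displacement_step: float = 0.355  # nm, auto-tuned during equilibration
    rotation_step: float = 1.0  # radians
    seed: int = 0
    equilibration_fraction: float = 0.30
    observe_every: int = 1
    tune_step: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise ValueError("equilibration_fraction must be in [0, 1)")
        if min(self.n_cycles, self.config_moves_per_cycle, self.reaction_moves_per_cycle) < 0:
            raise ValueError("counts must be non-negative")


class SystemState:
    """Mutable simulation state: box, ions, nanoparticle poses, site states.

    Ion positions live in ``ion_pos``/``ion_species``; nanoparticles are
    rigid bodies with center ``np_pos`` and orientation quaternion
    ``np_quat`` (scalar-last); ``site_ionized`` flags each surface site.
    World-frame site positions are cached and refreshed on rigid moves.
    """

    def __init__(
        self,
        box: BoxSpec,
        template: NanoparticleTemplate,
        np_pos: np.ndarray,
        np_quat: np.ndarray,
        ion_pos: np.ndarray,
        ion_species: np.ndarray,
        rng: np.random.Generator,
    ):
        self.box = box
        self.template = template
        self.np_pos = np.asarray(np_pos, dtype=float).reshape(-1, 3)
        self.np_quat = np.asarray(np_quat, dtype=float).reshape(-1, 4)
        self.ion_pos = np.asarray(ion_pos, dtype=float).reshape(-1, 3)
        self.ion_species = np.asarray(ion_species, dtype=int).reshape(-1)
        self.rng = rng
        self.n_np = len(self.np_pos)
        ns = template.n_sites
        self.site_ionized = np.zeros((self.n_np, ns), dtype=bool)
        self._site_pos = np.empty((self.n_np, ns, 3))
        for m in range(self.n_np):
            self._refresh_sites(m)

    # -- geometry -----------------------------------------------------------
    def _refresh_sites(self, m: int) -> None:
        pose = Pose(self.np_pos[m], self.np_quat[m] / np.linalg.norm(self.np_quat[m]))
        self._site_pos[m] = world_site_positions(self.template, pose)

    def site_positions(self) -> np.ndarray:
        """(n_np * n_sites, 3) world site positions."""
        return self._site_pos.reshape(-1, 3)

    def site_charges(self) -> np.ndarray:
        """Per-site charge in units of e (mode-dependent)."""
        mode = self.template.charge_mode
        if mode == "titrating":
            return np.where(self.site_ionized.reshape(-1), -1.0, 0.0)
        if mode == "fixed_fraction":
            return np.full(self.n_np * self.template.n_sites, -self.template.alpha_fixed)
        return np.zeros(self.n_np * self.template.n_sites)

    # -- species bookkeeping -------------------------------------------------
    def ion_count(self, name: str) -> int:
        return int(np.sum(self.ion_species == _CODE[name]))

    def species_count(self, name: str) -> int:
        """Count of an ion species or of the site states "HA"/"A"."""
        if name == "A":
            return int(np.sum(self.site_ionized))
        if name == "HA":
            return int(self.site_ionized.size - np.sum(self.site_ionized))
        return self.ion_count(name)

    def ion_charges(self) -> np.ndarray:
        return VALENCY[self.ion_species]

    def total_charge(self) -> float:
        return float(np.sum(self.ion_charges()) + np.sum(self.site_charges()))

    def alpha(self) -> float:
        return float(np.mean(self.site_ionized))

    def n_ions(self) -> int:
        return len(self.ion_species)

    # -- charge assembly ------------------------------------------------------
    def charge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Positions and charges of every charged entity (zero-q sites dropped)."""
        q_site = self.site_charges()
        live = q_site != 0.0
        pos = np.vstack([self.ion_pos, self.site_positions()[live]])
        q = np.concatenate([self.ion_charges(), q_site[live]])
        return pos, q


def _random_quat(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(rng=rng).as_quat()


def build_initial_state(
    box: BoxSpec,
    template: NanoparticleTemplate,
    n_np: int,
    n_salt_pairs: int,
    seed: int,
    model: EnergyModel | None = None,
    max_attempts: int = 1_000_000,
) -> SystemState:
    """Random non-overlapping initial configuration (rejection sampling).

    All sites start protonated (neutral particle) and the box holds
    ``n_salt_pairs`` NaCl pairs, so the initial state is exactly neutral.
    In fixed-fraction mode the per-particle charge is rounded so the total
    site charge is an integer, neutralized by extra Na+ counterions.
    """
    model = model or EnergyModel()
    rng = np.random.default_rng(seed)
    L = box.edge_length

    def overlaps(r: np.ndarray, others: np.ndarray, r_off: float) -> bool:
        if len(others) == 0:
            return False
        d = others - r
        d -= L * np.round(d / L)
        return bool(np.any(np.sum(d * d, axis=1) <= r_off**2))

    np_pos = np.empty((0, 3))
    attempts = 0
    while len(np_pos) < n_np:
        r = rng.uniform(0.0, L, size=3)
        if not overlaps(r, np_pos, model.offset(CORE, CORE)):
            np_pos = np.vstack([np_pos, r])
        attempts += 1
        if attempts > max_attempts:
            raise InitializationError("could not place nanoparticles without overlap")

    n_counter = 0
    if template.charge_mode == "fixed_fraction" and n_np > 0:
        # snap the fractional charge so that integer counterions neutralize it
        n_counter = int(round(template.alpha_fixed * template.n_sites * n_np))
        alpha_eff = n_counter / (template.n_sites * n_np)
        if alpha_eff != template.alpha_fixed:
            import dataclasses

            template = dataclasses.replace(template, alpha_fixed=alpha_eff)

    species = [_CODE["Na"]] * (n_salt_pairs + n_counter) + [_CODE["Cl"]] * n_salt_pairs
    ion_pos = np.empty((0, 3))
    while len(ion_pos) < len(species):
        r = rng.uniform(0.0, L, size=3)
        if overlaps(r, np_pos, model.offset(ION, CORE)):
            attempts += 1
        elif overlaps(r, ion_pos, model.offset(ION, ION)):
            attempts += 1
        else:
            ion_pos = np.vstack([ion_pos, r])
        if attempts > max_attempts:
            raise InitializationError("could not place ions without overlap")

    quats = np.array([_random_quat(rng) for _ in range(n_np)]).reshape(-1, 4)
    return SystemState(
        box=box,
        template=template,
        np_pos=np_pos,
        np_quat=quats,
        ion_pos=ion_pos,
        ion_species=np.array(species, dtype=int),
        rng=rng,
    )


class _Hamiltonian:
    """Incremental energy bookkeeping for one state under one mode.

    Tracks the WCA total, the Ewald real/reciprocal/self parts and the
    structure factor, updating them per accepted move; ``recompute()`` gives
    the from-scratch reference the increments are tested against.
    """

    def __init__(self, state: SystemState, model: EnergyModel, mode: str):
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        self.state = state
        self.model = model
        self.mode = mode
        self.coulomb_on = mode in ("full", "fixed_fraction")
        self.wca_on = mode != "no_interactions"
        self.L = state.box.edge_length
        if self.wca_on:
            cut = max(model.offsets.values()) + model.wca_cut
            if self.L < 2.0 * cut:
                raise ValueError(
                    f"box edge {self.L:.3f} nm violates minimum-image validity "
                    f"(needs > {2 * cut:.3f} nm)"
                )
        self.ewald = Ewald(self.L, model) if self.coulomb_on else None
        self.U_wca = 0.0
        self.U_real = 0.0
        self.U_recip = 0.0
        self.U_self = 0.0
        self.S = None
        if self.wca_on:
            self.U_wca = self.total_wca()
            if not np.isfinite(self.U_wca):
                raise InitializationError("initial configuration has hard overlaps")
        if self.coulomb_on:
            pos, q = state.charge_arrays()
            if abs(np.sum(q)) > 1e-9:
                raise ValueError("system must be electroneutral")
            self.S = self.ewald.structure_factor(pos, q)
            self.U_real = self.ewald.real_energy(pos, q)
            self.U_recip = self.ewald.recip_energy(self.S)
            self.U_self = self.ewald.self_energy(q)

    # -- totals ---------------------------------------------------------------
    @property
    def U_coulomb(self) -> float:
        return self.U_real + self.U_recip + self.U_self

    @property
    def U_total(self) -> float:
        return self.U_wca + self.U_coulomb

    def _min_image(self, d: np.ndarray) -> np.ndarray:
        return d - self.L * np.round(d / self.L)

    def _pair_dist(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        d = self._min_image(np.atleast_2d(a)[:, None, :] - np.atleast_2d(b)[None, :, :])
        return np.sqrt(np.sum(d * d, axis=-1))

    def total_wca(self) -> float:
        st, m = self.state, self.model
        u = 0.0
        if st.n_ions() > 1:
            r = self._pair_dist(st.ion_pos, st.ion_pos)
            iu = np.triu_indices(st.n_ions(), k=1)
            u += float(np.sum(wca_energy_array(r[iu], m.offset(ION, ION), m)))
        if st.n_ions() > 0 and st.n_np > 0:
            r = self._pair_dist(st.ion_pos, st.np_pos)
            u += float(np.sum(wca_energy_array(r, m.offset(ION, CORE), m)))
        if st.n_np > 1:
            r = self._pair_dist(st.np_pos, st.np_pos)
            iu = np.triu_indices(st.n_np, k=1)
            u += float(np.sum(wca_energy_array(r[iu], m.offset(CORE, CORE), m)))
        return u

    def recompute(self) -> dict:
        """Fresh full recomputation of every energy component."""
        out = {"U_wca": self.total_wca() if self.wca_on else 0.0}
        if self.coulomb_on:
            pos, q = self.state.charge_arrays()
            S = self.ewald.structure_factor(pos, q)
            out["U_real"] = self.ewald.real_energy(pos, q)
            out["U_recip"] = self.ewald.recip_energy(S)
            out["U_self"] = self.ewald.self_energy(q)
        else:
            out["U_real"] = out["U_recip"] = out["U_self"] = 0.0
        out["U_coulomb"] = out["U_real"] + out["U_recip"] + out["U_self"]
        out["U_total"] = out["U_wca"] + out["U_coulomb"]
        return out

    # -- WCA deltas -----------------------------------------------------------
    def wca_ion_energy(self, r: np.ndarray, exclude_ion: int | None = None) -> float:
        st, m = self.state, self.model
        u = 0.0
        if st.n_ions() > 0:
            d = self._pair_dist(r, st.ion_pos)[0]
            if exclude_ion is not None:
                d = np.delete(d, exclude_ion)
            u += float(np.sum(wca_energy_array(d, m.offset(ION, ION), m)))
            if not np.isfinite(u):
                return np.inf
        if st.n_np > 0:
            d = self._pair_dist(r, st.np_pos)[0]
            u += float(np.sum(wca_energy_array(d, m.offset(ION, CORE), m)))
        return u

    def wca_core_energy(self, r: np.ndarray, exclude_np: int | None = None) -> float:
        st, m = self.state, self.model
        u = 0.0
        if st.n_ions() > 0:
            d = self._pair_dist(r, st.ion_pos)[0]
            u += float(np.sum(wca_energy_array(d, m.offset(ION, CORE), m)))
            if not np.isfinite(u):
                return np.inf
        if st.n_np > 0:
            d = self._pair_dist(r, st.np_pos)[0]
            if exclude_np is not None:
                d = np.delete(d, exclude_np)
            u += float(np.sum(wca_energy_array(d, m.offset(CORE, CORE), m)))
        return u

    # -- Coulomb deltas ---------------------------------------------------------
    def coulomb_delta(
        self,
        removed_pos: np.ndarray,
        removed_q: np.ndarray,
        added_pos: np.ndarray,
        added_q: np.ndarray,
    ):
        """(dU, dS, dSelf-handled) for replacing one charge group by another.

        ``removed`` rows must currently be part of the system's charge set.
        Returns ``(dU_coul, dS, d_real, d_self)``; commit with
        :meth:`apply_coulomb`.
        """
        ew = self.ewald
        pos_all, q_all = self.state.charge_arrays()
        d_real = 0.0
        dS = np.zeros_like(self.S)
        if len(added_q):
            d_real += ew.cross_real_energy(added_pos, added_q, pos_all, q_all)
            if len(removed_q):
                d_real -= ew.cross_real_energy(added_pos, added_q, removed_pos, removed_q)
            if len(added_q) > 1:
                d_real += ew.real_energy(added_pos, added_q)
            dS += ew.phases(added_pos) @ added_q
        if len(removed_q):
            d_real -= ew.cross_real_energy(removed_pos, removed_q, pos_all, q_all)
            if len(removed_q) > 1:
                d_real += ew.real_energy(removed_pos, removed_q)
            dS -= ew.phases(removed_pos) @ removed_q
        d_self = ew.self_energy(added_q) - ew.self_energy(removed_q)
        d_recip = ew.recip_energy(self.S + dS) - self.U_recip
        return d_real + d_recip + d_self, dS, d_real, d_self

    def apply_coulomb(self, dS: np.ndarray, d_real: float, d_self: float) -> None:
        self.S = self.S + dS
        self.U_recip = self.ewald.recip_energy(self.S)
        self.U_real += d_real
        self.U_self += d_self


class Engine:
    """Drives the move mix over one :class:`SystemState`."""

    def __init__(
        self,
        state: SystemState,
        schedule: MCSchedule,
        model: EnergyModel,
        reservoir: ReservoirSpec,
        mode: str = "full",
    ):
        if mode == "fixed_fraction" and state.template.charge_mode != "fixed_fraction":
            raise ValueError("fixed_fraction mode needs a fixed_fraction template")
        self.state = state
        self.schedule = schedule
        self.model = model
        self.reservoir = reservoir
        self.mode = mode
        self.ham = _Hamiltonian(state, model, mode)
        self.reactions = self._build_reactions()
        self.volume_factor = (
            state.box.volume * AVOGADRO_PER_NM3_MOLAR
        )  # V N_A c0 with c0 = 1 mol/L
        self.displacement_step = schedule.displacement_step
        self.accept_counts = {"config": 0, "config_tried": 0, "reaction": 0, "reaction_tried": 0}

    def _build_reactions(self) -> list:
        rxns = []
        res = self.reservoir
        titrating = (
            self.state.template.charge_mode == "titrating"
            and self.mode != "fixed_fraction"
            and self.state.n_np > 0
        )
        if titrating:
            acids = composite_acid_constants(res, self.state.template.pKa)
            rxns += [
                ReactionSpec("acid_H", {"HA": -1, "A": 1, "H": 1}, acids["acid_H"]),
                ReactionSpec("acid_Na", {"HA": -1, "A": 1, "Na": 1}, acids["acid_Na"]),
                ReactionSpec("acid_OH", {"HA": -1, "A": 1, "OH": -1}, acids["acid_OH"]),
            ]
        pair_species = {"NaCl": ("Na", "Cl"), "HCl": ("H", "Cl"), "NaOH": ("Na", "OH"), "HOH": ("H", "OH")}
        for name, (i, j) in pair_species.items():
            rxns.append(ReactionSpec(name, {i: 1, j: 1}, res.constants[name]))
        return rxns

    # -- configurational moves -------------------------------------------------
    def attempt_displacement(self, index: int | None = None) -> bool:
        """Displace one ion or one nanoparticle (rigid) by a random step."""
        st, rng = self.state, self.state.rng
        n_obj = st.n_ions() + st.n_np
        if n_obj == 0:
            return False
        if index is None:
            index = int(rng.integers(n_obj))
        step = self.displacement_step * rng.uniform(-0.5, 0.5, size=3)
        if index < st.n_ions():
            return self._displace_ion(index, step)
        return self._displace_np(index - st.n_ions(), step)

    def _metropolis(self, dU: float) -> bool:
        if not np.isfinite(dU):
            return False
        if dU <= 0:
            return True
        return self.state.rng.random() < np.exp(-dU)

    def _displace_ion(self, i: int, step: np.ndarray) -> bool:
        st = self.state
        old = st.ion_pos[i].copy()
        new = (old + step) % st.box.edge_length
        dU = 0.0
        if self.ham.wca_on:
            u_new = self.ham.wca_ion_energy(new, exclude_ion=i)
            if not np.isfinite(u_new):
                return False
            u_old = self.ham.wca_ion_energy(old, exclude_ion=i)
            dU += u_new - u_old
        coul = None
        if self.ham.coulomb_on:
            q = np.array([VALENCY[st.ion_species[i]]])
            dU_c, dS, d_real, d_self = self.ham.coulomb_delta(
                old[None, :], q, new[None, :], q
            )
            dU += dU_c
            coul = (dS, d_real, d_self)
        if not self._metropolis(dU):
            return False
        st.ion_pos[i] = new
        if self.ham.wca_on:
            self.ham.U_wca += u_new - u_old
        if coul is not None:
            self.ham.apply_coulomb(*coul)
        return True

    def _rigid_np_update(self, m: int, new_center: np.ndarray, new_quat: np.ndarray | None) -> bool:
        """Shared accept/reject logic for nanoparticle displacement/rotation."""
        st = self.state
        old_center = st.np_pos[m].copy()
        old_quat = st.np_quat[m].copy()
        old_sites = st._site_pos[m].copy()
        dU = 0.0
        u_new = u_old = 0.0
        if self.ham.wca_on:
            u_new = self.ham.wca_core_energy(new_center, exclude_np=m)
            if not np.isfinite(u_new):
                return False
            u_old = self.ham.wca_core_energy(old_center, exclude_np=m)
            dU += u_new - u_old
        coul = None
        q_site = st.site_charges().reshape(st.n_np, -1)[m]
        live = q_site != 0.0
        if self.ham.coulomb_on and np.any(live):
            # tentatively update the pose to get new site positions
            st.np_pos[m] = new_center
            if new_quat is not None:
                st.np_quat[m] = new_quat
            st._refresh_sites(m)
            new_sites = st._site_pos[m].copy()
            # restore before computing the delta (charge_arrays must see "old")
            st.np_pos[m] = old_center
            st.np_quat[m] = old_quat
            st._site_pos[m] = old_sites
            dU_c, dS, d_real, d_self = self.ham.coulomb_delta(
                old_sites[live], q_site[live], new_sites[live], q_site[live]
            )
            dU += dU_c
            coul = (dS, d_real, d_self)
        if not self._metropolis(dU):
            return False
        st.np_pos[m] = new_center
        if new_quat is not None:
            st.np_quat[m] = new_quat
        st._refresh_sites(m)
        if self.ham.wca_on:
            self.ham.U_wca += u_new - u_old
        if coul is not None:
            self.ham.apply_coulomb(*coul)
        return True

    def _displace_np(self, m: int, step: np.ndarray) -> bool:
        st = self.state
        new_center = (st.np_pos[m] + step) % st.box.edge_length
        return self._rigid_np_update(m, new_center, None)

    def attempt_rotation(self, m: int | None = None) -> bool:
        """Rotate one nanoparticle by a random small angle (symmetric proposal)."""
        st, rng = self.state, self.state.rng
        if st.n_np == 0:
            return False
        if m is None:
            m = int(rng.integers(st.n_np))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0.0, self.schedule.rotation_step)
        dq = Rotation.from_rotvec(angle * axis)
        new_quat = (dq * Rotation.from_quat(st.np_quat[m])).as_quat()
        new_quat /= np.linalg.norm(new_quat)
        return self._rigid_np_update(m, st.np_pos[m].copy(), new_quat)

    # -- reaction / exchange moves ----------------------------------------------
    def _combinatorial_factor(self, rxn: ReactionSpec, xi: int) -> float | None:
        """prod_i N_i!/(N_i + xi nu_i)! for unit stoichiometries; None = reject."""
        fac = 1.0
        for name, nu in rxn.stoichiometry.items():
            n = self.state.species_count(name)
            change = xi * nu
            if change == -1:
                if n == 0:
                    return None
                fac *= n
            elif change == 1:
                fac *= 1.0 / (n + 1)
            else:  # pragma: no cover - only unit stoichiometries are used
                raise NotImplementedError
        return fac

    def attempt_reaction(self, rxn: ReactionSpec, xi: int) -> bool:
        """One reaction-ensemble trial in direction xi (+1 forward)."""
        st, rng = self.state, self.state.rng
        fac = self._combinatorial_factor(rxn, xi)
        if fac is None:
            return False

        # plan the microscopic changes
        flip_site = None  # (m, s, new_state)
        insert_ions: list[tuple[str, np.ndarray]] = []
        delete_ions: list[int] = []
        for name, nu in rxn.stoichiometry.items():
            change = xi * nu
            if name == "A" or name == "HA":
                continue
            if change == +1:
                insert_ions.append((name, rng.uniform(0.0, st.box.edge_length, size=3)))
            elif change == -1:
                cands = np.flatnonzero(st.ion_species == _CODE[name])
                delete_ions.append(int(cands[rng.integers(len(cands))]))
        if "A" in rxn.stoichiometry:
            want = xi * rxn.stoichiometry["A"]  # +1: HA -> A-, -1: A- -> HA
            pool = np.flatnonzero(~st.site_ionized.reshape(-1) if want > 0 else st.site_ionized.reshape(-1))
            k = int(pool[rng.integers(len(pool))])
            flip_site = (k // st.template.n_sites, k % st.template.n_sites, want > 0)

        dU = 0.0
        u_wca_new = 0.0
        u_wca_removed = 0.0
        if self.ham.wca_on:
            for _, r in insert_ions:
                u = self.ham.wca_ion_energy(r)
                if not np.isfinite(u):
                    return False
                u_wca_new += u
            # interactions among simultaneously inserted ions
            if len(insert_ions) == 2:
                d = self._dist(insert_ions[0][1], insert_ions[1][1])
                u = float(
                    wca_energy_array(
                        np.array([d]), self.model.offset(ION, ION), self.model
                    )[0]
                )
                if not np.isfinite(u):
                    return False
                u_wca_new += u
            for idx in delete_ions:
                u_wca_removed += self.ham.wca_ion_energy(st.ion_pos[idx], exclude_ion=idx)
            if len(delete_ions) == 2:
                u_wca_removed -= float(
                    wca_energy_array(
                        np.array([self._dist(st.ion_pos[delete_ions[0]], st.ion_pos[delete_ions[1]])]),
                        self.model.offset(ION, ION),
                        self.model,
                    )[0]
                )
            dU += u_wca_new - u_wca_removed

        coul = None
        if self.ham.coulomb_on:
            rm_pos, rm_q, add_pos, add_q = [], [], [], []
            for name, r in insert_ions:
                add_pos.append(r)
                add_q.append(VALENCY[_CODE[name]])
            for idx in delete_ions:
                rm_pos.append(st.ion_pos[idx])
                rm_q.append(VALENCY[st.ion_species[idx]])
            if flip_site is not None:
                m, s, ionize = flip_site
                r_site = st._site_pos[m, s]
                if ionize:
                    add_pos.append(r_site)
                    add_q.append(-1.0)
                else:
                    rm_pos.append(r_site)
                    rm_q.append(-1.0)
            dU_c, dS, d_real, d_self = self.ham.coulomb_delta(
                np.array(rm_pos).reshape(-1, 3),
                np.array(rm_q),
                np.array(add_pos).reshape(-1, 3),
                np.array(add_q),
            )
            dU += dU_c
            coul = (dS, d_real, d_self)

        p_acc = rxn.K**xi * fac * self.volume_factor ** (xi * rxn.nu_bar)
        if np.isfinite(dU):
            p_acc *= np.exp(-float(np.clip(dU, -700.0, 700.0)))
        else:
            p_acc = 0.0
        if rng.random() >= min(1.0, p_acc):
            return False

        # commit
        if flip_site is not None:
            m, s, ionize = flip_site
            st.site_ionized[m, s] = ionize
        if delete_ions:
            keep = np.ones(st.n_ions(), dtype=bool)
            keep[delete_ions] = False
            st.ion_pos = st.ion_pos[keep]
            st.ion_species = st.ion_species[keep]
        for name, r in insert_ions:
            st.ion_pos = np.vstack([st.ion_pos, r])
            st.ion_species = np.append(st.ion_species, _CODE[name])
        if self.ham.wca_on:
            self.ham.U_wca += u_wca_new - u_wca_removed
        if coul is not None:
            self.ham.apply_coulomb(*coul)
        return True

    def _dist(self, a: np.ndarray, b: np.ndarray) -> float:
        d = a - b
        d -= self.state.box.edge_length * np.round(d / self.state.box.edge_length)
        return float(np.sqrt(np.sum(d * d)))

    # -- driver -------------------------------------------------------------
    def run_cycle(self) -> None:
        rng = self.state.rng
        n_cfg = self.schedule.config_moves_per_cycle
        n_rxn = self.schedule.reaction_moves_per_cycle
        n_np = self.state.n_np
        for _ in range(n_cfg):
            self.accept_counts["config_tried"] += 1
            # nanoparticles get displacement and rotation slots; ions one each
            n_slots = self.state.n_ions() + 2 * n_np
            if n_slots == 0:
                break
            slot = int(rng.integers(n_slots))
            if slot < self.state.n_ions() + n_np:
                ok = self.attempt_displacement(slot)
            else:
                ok = self.attempt_rotation(slot - self.state.n_ions() - n_np)
            self.accept_counts["config"] += ok
        for _ in range(n_rxn):
            self.accept_counts["reaction_tried"] += 1
            rxn = self.reactions[int(rng.integers(len(self.reactions)))]
            xi = 1 if rng.random() < 0.5 else -1
            self.accept_counts["reaction"] += self.attempt_reaction(rxn, xi)

    def tune_displacement(self) -> None:
        tried = self.accept_counts["config_tried"]
        if tried < 50:
            return
        rate = self.accept_counts["config"] / tried
        if rate < 0.30:
            self.displacement_step = max(0.1 * self.model.sigma, self.displacement_step * 0.8)
        elif rate > 0.50:
            self.displacement_step = min(
                self.state.box.edge_length / 4.0, self.displacement_step * 1.2
            )
        self.accept_counts["config"] = 0
        self.accept_counts["config_tried"] = 0


def run(
    state: SystemState,
    schedule: MCSchedule,
    model: EnergyModel,
    reservoir: ReservoirSpec,
    mode: str = "full",
) -> ObservableSeries:
    """Run the move schedule and collect the observable series.

    Step sizes are auto-tuned toward 30-50% acceptance during the
    equilibration fraction of the run and frozen afterwards (tuning during
    production would violate detailed balance).  Bitwise reproducible for a
    fixed seed.
    """
    engine = Engine(state, schedule, model, reservoir, mode)
    records = []

    def record(cycle: int) -> None:
        records.append(
            {
                "cycle": cycle,
                "alpha": state.alpha() if state.n_np > 0 else np.nan,
                "N_Na": state.ion_count("Na"),
                "N_Cl": state.ion_count("Cl"),
                "N_H": state.ion_count("H"),
                "N_OH": state.ion_count("OH"),
                "U_total": engine.ham.U_total,
                "U_coulomb": engine.ham.U_coulomb,
            }
        )

    record(0)
    n_equil = int(np.floor(schedule.equilibration_fraction * schedule.n_cycles))
    for cycle in range(1, schedule.n_cycles + 1):
        engine.run_cycle()
        if schedule.tune_step and cycle <= n_equil and cycle % 25 == 0:
            engine.tune_displacement()
        if cycle % schedule.observe_every == 0:
            record(cycle)

    frame = pd.DataFrame.from_records(records)
    return ObservableSeries(
        frame=frame,
        volume=state.box.volume,
        reservoir_conc=dict(reservoir.conc),
        equilibration_fraction=schedule.equilibration_fraction,
        metadata={
            "mode": mode,
            "seed": schedule.seed,
            "n_cycles": schedule.n_cycles,
            "final_step": engine.displacement_step,
        },
    )
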