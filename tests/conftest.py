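"""Shared fixtures: the expensive simulation runs reused across the suite.

All runs are deliberately desk-scale (few nanoparticles, tens of salt pairs,
hundreds of cycles); state points were chosen so the probed effect is well
resolved at this scale.  Seeds are fixed for reproducibility.
"""

from __future__ import annotations

import numpy as np
import pytest

from patchtitrate.energy import EnergyModel
from patchtitrate.geometry import (
    AVOGADRO_PER_NM3_MOLAR,
    NanoparticleTemplate,
    box_from_salt,
)
from patchtitrate.mc_engine import MCSchedule, build_initial_state, run
from patchtitrate.reservoir import solve_reservoir
from patchtitrate.steric import StericRunSpec, widom_D_plus
from patchtitrate.theory import coupled_hh_donnan


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture(scope="session")
def ideal_runs(model):
    """No-interactions runs at 3 state points vs the HH+Donnan solver.

    10 nanoparticles, 50 salt pairs, 500 cycles each; ideal reservoir so the
    engine's stationary distribution is exactly the ideal Donnan ensemble.
    """
    out = []
    for ph, cs in [(3.5, 0.1), (4.0, 0.1), (5.0, 0.05)]:
        res = solve_reservoir(ph, cs, activity_model="ideal")
        box = box_from_salt(cs, 50)
        tmpl = NanoparticleTemplate.build(n_sites=10, pKa=4.0, seed=0)
        state = build_initial_state(box, tmpl, 10, 50, 11, model)
        sched = MCSchedule(
            n_cycles=500, config_moves_per_cycle=20, reaction_moves_per_cycle=250, seed=11
        )
        summary = run(state, sched, model, res, mode="no_interactions").summary()
        c_acid = 10 * 10 / (box.volume * AVOGADRO_PER_NM3_MOLAR)
        theory = coupled_hh_donnan(ph, 4.0, c_acid, cs)
        out.append({"pH": ph, "c_salt": cs, "sim": summary, "theory": theory})
    return out


@pytest.fixture(scope="session")
def theta_runs(model):
    """Fully interacting runs at three degrees of patchiness, same state point."""
    out = {}
    for theta in (0.0, 0.5, 0.9):
        res = solve_reservoir(5.0, 0.05)
        box = box_from_salt(0.05, 20)
        tmpl = NanoparticleTemplate.build(n_sites=10, theta=theta, pKa=4.0, seed=3)
        state = build_initial_state(box, tmpl, 3, 20, 21, model)
        sched = MCSchedule(
            n_cycles=200, config_moves_per_cycle=60, reaction_moves_per_cycle=40, seed=21
        )
        out[theta] = run(state, sched, model, res, mode="full").summary()
    return out


@pytest.fixture(scope="session")
def titration_pair(model):
    """Titrating run plus its fixed-fractional-charge twin (same state point).

    The fixed run reuses the mean ionization degree measured in the
    titrating run as its constant per-site charge.
    """
    res = solve_reservoir(5.0, 0.05)
    box = box_from_salt(0.05, 30)
    sched = MCSchedule(
        n_cycles=300, config_moves_per_cycle=80, reaction_moves_per_cycle=50, seed=31
    )
    tmpl = NanoparticleTemplate.build(n_sites=10, theta=0.0, pKa=4.0, seed=4)
    state = build_initial_state(box, tmpl, 5, 30, 31, model)
    s_tit = run(state, sched, model, res, mode="full").summary()

    tmpl_ff = NanoparticleTemplate.build(
        n_sites=10,
        theta=0.0,
        pKa=4.0,
        seed=4,
        charge_mode="fixed_fraction",
        alpha_fixed=s_tit["alpha_mean"],
    )
    state_ff = build_initial_state(box, tmpl_ff, 5, 30, 32, model)
    s_ff = run(state_ff, sched, model, res, mode="fixed_fraction").summary()
    return s_tit, s_ff


@pytest.fixture(scope="session")
def lowsalt_run(model):
    """Interacting run at low salt: enough free H+ to resolve D_H."""
    res = solve_reservoir(3.5, 0.01)
    box = box_from_salt(0.01, 20)
    tmpl = NanoparticleTemplate.build(n_sites=10, theta=0.5, pKa=4.0, seed=5)
    state = build_initial_state(box, tmpl, 5, 20, 41, model)
    sched = MCSchedule(
        n_cycles=300, config_moves_per_cycle=80, reaction_moves_per_cycle=50, seed=41
    )
    series = run(state, sched, model, res, mode="full")
    return state, series.summary()


@pytest.fixture(scope="session")
def moderate_run(model):
    """Interacting run at 0.1 M salt and weak Donnan coupling.

    At this state point the compartments' salt activity coefficients nearly
    match, so the ideal reciprocity D+ D- = 1 should hold within sampling
    error.
    """
    res = solve_reservoir(3.5, 0.1)
    box = box_from_salt(0.1, 30)
    tmpl = NanoparticleTemplate.build(n_sites=10, theta=0.0, pKa=4.0, seed=6)
    state = build_initial_state(box, tmpl, 4, 30, 61, model)
    sched = MCSchedule(
        n_cycles=250, config_moves_per_cycle=80, reaction_moves_per_cycle=50, seed=61
    )
    return run(state, sched, model, res, mode="full").summary()


@pytest.fixture(scope="session")
def widom_main():
    """Widom-insertion partition ratio at phi = 0.1, size ratio 8."""
    spec = StericRunSpec(
        phi_np=0.1, d_np=8 * 0.355, n_insertions=1000, n_configs=100, seed=1
    )
    D, se = widom_D_plus(spec)
    return {"D": D, "SE": se, "spec": spec}


def joint_z(a, sa, b, sb):
    denom = np.hypot(sa, sb)
    return abs(a - b) / denom if denom > 0 else np.inf
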