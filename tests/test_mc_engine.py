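"""Engine-level oracles: ideal limits, detailed balance, bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.spatial.transform import Rotation
from scipy.stats import binomtest

from patchtitrate.energy import EnergyModel
from patchtitrate.geometry import (
    AVOGADRO_PER_NM3_MOLAR,
    BoxSpec,
    NanoparticleTemplate,
    box_from_salt,
)
from patchtitrate.mc_engine import Engine, MCSchedule, build_initial_state, run
from patchtitrate.observables import blocking_error
from patchtitrate.reservoir import solve_reservoir
from patchtitrate.theory import coupled_hh_donnan


@pytest.fixture(scope="module")
def model():
    return EnergyModel()


def _engine(
    model,
    pH=7.0,
    c_salt=0.1,
    n_pairs=50,
    n_np=1,
    template=None,
    seed=0,
    mode="no_interactions",
    ideal_reservoir=True,
    **sched_kw,
):
    res = solve_reservoir(pH, c_salt, activity_model="ideal" if ideal_reservoir else "davies")
    box = box_from_salt(c_salt, n_pairs)
    template = template or NanoparticleTemplate.build(n_sites=1, seed=0)
    state = build_initial_state(box, template, n_np, n_pairs, seed, model)
    sched = MCSchedule(seed=seed, **sched_kw)
    return Engine(state, sched, model, res, mode=mode), res, box


class TestReactionAcceptance:
    def test_forward_probability_one_in_matched_ideal_system(self, model):
        # K_A V N_A c0 = 1 with a single HA site and empty box makes the
        # forward acceptance factor exactly one
        box = box_from_salt(0.1, 50)
        vf = box.volume * AVOGADRO_PER_NM3_MOLAR
        pka = float(np.log10(vf))
        tmpl = NanoparticleTemplate.build(n_sites=1, pKa=pka, seed=0)
        for seed in range(10):
            eng, _, _ = _engine(model, n_pairs=50, template=tmpl, seed=seed)
            acid = eng.reactions[0]
            assert acid.name == "acid_H"
            assert eng.attempt_reaction(acid, +1) is True

    def test_reverse_rejected_without_free_protons(self, model):
        eng, _, _ = _engine(model)
        st = eng.state
        # ionize the site by hand and neutralize with one sodium ion
        st.site_ionized[0, 0] = True
        st.ion_pos = np.vstack([st.ion_pos, [[1.0, 1.0, 1.0]]])
        st.ion_species = np.append(st.ion_species, 0)  # Na+
        assert st.ion_count("H") == 0
        acid = eng.reactions[0]
        assert eng.attempt_reaction(acid, -1) is False

    def test_two_state_chain_matches_analytic_stationary_law(self, model):
        # single site, ideal: pi(ionized) = K V F / (1 + K V F); choose
        # K V F = 1/4 so forward acceptance is 1/4 and reverse is 1
        box = box_from_salt(0.1, 50)
        vf = box.volume * AVOGADRO_PER_NM3_MOLAR
        pka = float(-np.log10(0.25 / vf))
        tmpl = NanoparticleTemplate.build(n_sites=1, pKa=pka, seed=0)
        eng, _, _ = _engine(model, template=tmpl, seed=123)
        acid = eng.reactions[0]
        rng = np.random.default_rng(99)
        occ, from0, acc0, from1, acc1 = [], 0, 0, 0, 0
        for _ in range(6000):
            state_now = eng.state.species_count("A")
            xi = 1 if rng.random() < 0.5 else -1
            ok = eng.attempt_reaction(acid, xi)
            if state_now == 0 and xi == 1:
                from0 += 1
                acc0 += ok
            elif state_now == 1 and xi == -1:
                from1 += 1
                acc1 += ok
            occ.append(eng.state.species_count("A"))
        r = blocking_error(np.asarray(occ, dtype=float), equilibration_fraction=0.1)
        assert abs(r.mean - 0.2) < 3 * max(r.se, 1e-3)
        # empirical per-direction acceptance rates against the analytic ones
        assert binomtest(acc0, from0, 0.25).pvalue > 0.01
        assert binomtest(acc1, from1, 1.0 - 1e-12).pvalue > 0.01

    def test_ideal_titration_follows_coupled_theory_at_pKa(self, model):
        tmpl = NanoparticleTemplate.build(n_sites=10, pKa=4.0, seed=0)
        eng, res, box = _engine(
            model,
            pH=4.0,
            n_pairs=100,
            template=tmpl,
            seed=17,
            n_cycles=300,
            config_moves_per_cycle=0,
            reaction_moves_per_cycle=150,
        )
        series = run(eng.state, eng.schedule, model, res, mode="no_interactions")
        s = series.summary()
        c_acid = 10 / (box.volume * AVOGADRO_PER_NM3_MOLAR)
        th = coupled_hh_donnan(4.0, 4.0, c_acid, 0.1)
        assert abs(s["alpha_mean"] - th.alpha) < 3 * s["alpha_SE"]
        assert s["alpha_mean"] == pytest.approx(0.5, abs=0.05)


class TestGrandCanonicalIdeal:
    def test_bare_reservoir_concentrations_recovered(self, model):
        # auxiliary simulation of the reservoir alone: ideal-gas GCMC must
        # reproduce the target composition
        eng, res, _ = _engine(
            model,
            pH=5.0,
            n_pairs=50,
            n_np=0,
            seed=7,
            n_cycles=400,
            config_moves_per_cycle=0,
            reaction_moves_per_cycle=100,
        )
        series = run(eng.state, eng.schedule, model, res, mode="no_interactions")
        for sp in ("Na", "Cl", "H"):
            c = series.concentration(sp)
            target = res.conc[sp]
            assert abs(c.mean - target) <= 3 * max(c.se, 0.02 * target + 1e-9)


class TestConservationAndBookkeeping:
    def test_neutrality_exact_and_energy_increments_consistent(self, model):
        res = solve_reservoir(5.0, 0.05)
        box = box_from_salt(0.05, 10)
        tmpl = NanoparticleTemplate.build(n_sites=10, theta=0.5, pKa=4.0, seed=1)
        state = build_initial_state(box, tmpl, 2, 10, 13, model)
        sched = MCSchedule(
            n_cycles=40, config_moves_per_cycle=20, reaction_moves_per_cycle=20, seed=13
        )
        eng = Engine(state, sched, model, res, mode="full")
        for _ in range(40):
            eng.run_cycle()
            assert state.total_charge() == 0.0  # exact integer arithmetic
        rec = eng.ham.recompute()
        n = state.n_ions() + tmpl.n_sites * state.n_np
        assert abs(eng.ham.U_total - rec["U_total"]) < 1e-6 * max(n, 1)
        assert abs(eng.ham.U_coulomb - rec["U_coulomb"]) < 1e-6 * max(n, 1)

    def test_insertion_then_deletion_energy_cancels(self, model):
        res = solve_reservoir(5.0, 0.1)
        box = box_from_salt(0.1, 20)
        tmpl = NanoparticleTemplate.build(n_sites=5, theta=0.5, pKa=4.0, seed=2)
        state = build_initial_state(box, tmpl, 1, 20, 3, model)
        sched = MCSchedule(seed=3)
        eng = Engine(state, sched, model, res, mode="full")
        P = np.array([[1.0, 2.0, 3.0], [2.5, 2.0, 3.0]])
        Q = np.array([1.0, -1.0])
        empty_p, empty_q = np.empty((0, 3)), np.empty(0)
        d1, dS, d_real, d_self = eng.ham.coulomb_delta(empty_p, empty_q, P, Q)
        eng.ham.apply_coulomb(dS, d_real, d_self)
        # the Hamiltonian's "current" charge set is read off the state
        state.ion_pos = np.vstack([state.ion_pos, P])
        state.ion_species = np.append(state.ion_species, [0, 1])  # Na+, Cl-
        d2, _, _, _ = eng.ham.coulomb_delta(P, Q, empty_p, empty_q)
        assert d1 + d2 == pytest.approx(0.0, abs=1e-8)

    def test_null_replacement_is_zero_energy(self, model):
        res = solve_reservoir(5.0, 0.1)
        box = box_from_salt(0.1, 20)
        tmpl = NanoparticleTemplate.build(n_sites=5, seed=2)
        state = build_initial_state(box, tmpl, 1, 20, 3, model)
        eng = Engine(state, MCSchedule(seed=3), model, res, mode="full")
        P = state.ion_pos[:2].copy()
        Q = state.ion_charges()[:2].copy()
        dU, _, _, _ = eng.ham.coulomb_delta(P, Q, P, Q)
        assert dU == pytest.approx(0.0, abs=1e-10)

    def test_hard_overlap_is_certain_rejection(self, model):
        res = solve_reservoir(5.0, 0.1)
        box = box_from_salt(0.1, 20)
        tmpl = NanoparticleTemplate.build(seed=0)
        state = build_initial_state(box, tmpl, 1, 20, 5, model)
        eng = Engine(state, MCSchedule(seed=5), model, res, mode="full")
        u = eng.ham.wca_ion_energy(state.np_pos[0])  # dead center of the core
        assert np.isinf(u)
        assert eng._metropolis(np.inf) is False


class TestConfigurationalSampling:
    def test_pair_distance_histogram_matches_boltzmann_weight(self, model):
        # two WCA ions in a periodic box: p(r) ~ r^2 exp(-U(r)) for r < L/2
        res = solve_reservoir(7.0, 0.1, activity_model="ideal")
        box = BoxSpec(edge_length=3.0)
        tmpl = NanoparticleTemplate.build(n_sites=1, seed=0)
        state = build_initial_state(box, tmpl, 0, 1, 29, model)
        sched = MCSchedule(
            n_cycles=1,
            config_moves_per_cycle=10,
            reaction_moves_per_cycle=0,
            seed=29,
            tune_step=False,
            displacement_step=0.9,
        )
        eng = Engine(state, sched, model, res, mode="no_electrostatics")
        samples = []
        for _ in range(4000):
            eng.run_cycle()
            d = state.ion_pos[0] - state.ion_pos[1]
            d -= 3.0 * np.round(d / 3.0)
            samples.append(np.linalg.norm(d))
        samples = np.asarray(samples)
        edges = np.array([0.30, 0.42, 0.70, 1.00, 1.30])
        counts = np.histogram(samples, bins=edges)[0]

        def weight(r):
            sr6 = (model.sigma / r) ** 6
            u = np.where(r < model.wca_cut, 4 * (sr6**2 - sr6) + 1.0, 0.0)
            return r**2 * np.exp(-u)

        probs = np.array(
            [integrate.quad(weight, a, b)[0] for a, b in zip(edges[:-1], edges[1:])]
        )
        probs /= probs.sum()
        n = counts.sum()
        for obs, p in zip(counts, probs):
            se = np.sqrt(n * p * (1 - p))
            assert abs(obs - n * p) < 4 * se

    def test_orientation_isotropic_in_symmetric_environment(self, model):
        # a charged-patch particle in isotropic salt has no preferred axis
        res = solve_reservoir(5.0, 0.05)
        box = box_from_salt(0.05, 5)
        tmpl = NanoparticleTemplate.build(
            n_sites=10, theta=0.9, seed=3, charge_mode="fixed_fraction", alpha_fixed=1.0
        )
        state = build_initial_state(box, tmpl, 1, 5, 37, model)
        sched = MCSchedule(
            n_cycles=1, config_moves_per_cycle=40, reaction_moves_per_cycle=0, seed=37
        )
        eng = Engine(state, sched, model, res, mode="fixed_fraction")
        zs = []
        for _ in range(300):
            eng.run_cycle()
            axis = Rotation.from_quat(state.np_quat[0]).apply([0.0, 0.0, 1.0])
            zs.append(axis[2])
        r = blocking_error(np.asarray(zs), equilibration_fraction=0.1)
        assert abs(r.mean) < 3 * max(r.se, 0.05)


class TestRunDriver:
    def test_zero_cycles_returns_initial_observables(self, model):
        eng, res, _ = _engine(model, n_cycles=0, seed=2)
        series = run(eng.state, eng.schedule, model, res, mode="no_interactions")
        assert len(series.frame) == 1
        assert series.frame["cycle"].iloc[0] == 0

    def test_bitwise_reproducible_for_fixed_seed(self, model):
        frames = []
        for _ in range(2):
            eng, res, _ = _engine(
                model,
                pH=4.5,
                n_pairs=30,
                seed=77,
                n_cycles=50,
                config_moves_per_cycle=5,
                reaction_moves_per_cycle=40,
                template=NanoparticleTemplate.build(n_sites=10, pKa=4.0, seed=1),
            )
            frames.append(run(eng.state, eng.schedule, model, res, mode="no_interactions").frame)
        pd.testing.assert_frame_equal(frames[0], frames[1])

    def test_fixed_fraction_charge_is_neutralized_by_counterions(self, model):
        box = box_from_salt(0.1, 20)
        tmpl = NanoparticleTemplate.build(
            n_sites=10, seed=4, charge_mode="fixed_fraction", alpha_fixed=0.73
        )
        state = build_initial_state(box, tmpl, 3, 20, 9, model)
        assert state.total_charge() == pytest.approx(0.0, abs=1e-12)
        # snapped so that 0.73 * 30 rounds to an integer counterion count
        assert state.template.alpha_fixed == pytest.approx(22 / 30)

    def test_unknown_mode_rejected(self, model):
        eng, res, _ = _engine(model, seed=1)
        with pytest.raises(ValueError):
            run(eng.state, eng.schedule, model, res, mode="langevin")
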