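"""Scheduler semantics: initialization, complex lifecycle, conservation,
determinism and extinction."""

import math

import numpy as np
import pytest

import rpsim
from rpsim import (
    KineticParams,
    MutationParams,
    ScenarioConfig,
    TorusGeometry,
    WorldState,
    attempt_complex_formation,
    initialize_world,
    make_state,
)
from rpsim import engine as eng
from rpsim import _kernel as K
from rpsim.world import PARASITE, REPLICASE, Molecule, torus_distance


def small_config(**over):
    cfg = ScenarioConfig(width=32.0, height=32.0, n_replicases=60,
                         n_parasites=60, disc_radius=10.0, max_steps=200,
                         decay_mode="frozen", offspring_offset=0.0, seed=5)
    for k, v in over.items():
        setattr(cfg, k, v)
    return cfg


def make_world(kin, width=32.0, decay_mode="ticking", seed=1):
    return WorldState(TorusGeometry(width, width), kin, make_state(seed),
                      decay_mode=decay_mode)


def step_n(state, kin, n, mut=None, offset=0.0):
    mut = mut or MutationParams()
    logs = []
    for _ in range(n):
        _, log = eng.step(state, kin, mut, offspring_offset=offset)
        logs.append(log)
    return logs


class TestInitialization:
    def test_circle_mode_places_species_in_opposite_half_discs(self):
        cfg = small_config(n_replicases=100, n_parasites=100)
        state = initialize_world(cfg)
        mols = state.free_molecules()
        assert len(mols) == 200
        cx, cy = cfg.width / 2, cfg.height / 2
        for m in mols:
            r = math.hypot(m.x - cx, m.y - cy)
            assert r <= cfg.disc_radius + 1e-9
            if m.species == REPLICASE:
                assert m.y >= cy - 1e-9
            else:
                assert m.y <= cy + 1e-9
        assert sum(m.species == REPLICASE for m in mols) == 100
        # shared initial attributes
        assert {(m.a, m.l) for m in mols if m.species == REPLICASE} == {(0.7, 0.0)}
        assert {(m.a, m.l) for m in mols if m.species == PARASITE} == {(0.55, 0.2)}

    def test_random_mode_covers_arena(self):
        cfg = small_config(placement="random", n_replicases=300, n_parasites=300,
                           width=64.0, height=64.0)
        state = initialize_world(cfg)
        xs = np.array([m.x for m in state.free_molecules()])
        ys = np.array([m.y for m in state.free_molecules()])
        assert xs.min() < 8 and xs.max() > 56
        assert ys.min() < 8 and ys.max() > 56

    def test_initial_lifetimes_are_exponential(self):
        cfg = ScenarioConfig(width=128.0, height=128.0, n_replicases=5000,
                             n_parasites=5000, placement="random",
                             max_steps=10, seed=3)
        state = initialize_world(cfg)
        rlts = np.array([m.rlt for m in state.free_molecules()])
        d = cfg.kinetics.d
        se = (1 / d) / math.sqrt(len(rlts))
        assert abs(rlts.mean() - 1 / d) < 3 * se

    def test_zero_parasites_terminates_at_step_zero(self):
        cfg = small_config(n_parasites=0)
        res = rpsim.run(cfg)
        assert res.outcome == "extinct_parasites"
        assert res.final_step == 0

    def test_overdense_initialization_rejected(self):
        cfg = small_config(n_replicases=4000, n_parasites=4000, disc_radius=5.0)
        with pytest.raises(ValueError):
            initialize_world(cfg)


class TestHandTraces:
    def test_lifetime_five_expires_at_step_five(self):
        """A lone molecule with rlt = 5.0 and D = 0 dies at the start of
        step 5, leaving the world empty."""
        kin = KineticParams(d=0.182, D=0.0, D_complex=0.0)
        state = make_world(kin)
        state.add_molecule(REPLICASE, 5.0, 5.0, 0.7, 0.0, 5.0)
        for i in range(4):
            _, log = eng.step(state, kin, MutationParams())
            assert state.n_molecules() == 1, f"alive through step {i+1}"
        _, log = eng.step(state, kin, MutationParams())
        assert log.decays_free == 1
        assert state.n_molecules() == 0

    def test_two_replicases_form_then_replicate(self):
        """Two replicases 0.5 apart with a=1, l=0, no decay: a complex
        forms in step 1, replication fires in step 2 (ttr ~ 4e-6 < dt),
        leaving three free replicases."""
        kin = KineticParams(d=0.0, D=0.0, D_complex=0.0)
        state = make_world(kin, seed=8)
        state.add_molecule(REPLICASE, 5.0, 5.0, 1.0, 0.0, K.INF)
        state.add_molecule(REPLICASE, 5.5, 5.0, 1.0, 0.0, K.INF)
        _, log1 = eng.step(state, kin, MutationParams(), offspring_offset=1.0)
        assert log1.complex_formations == 1
        assert len(state.complexes()) == 1
        assert state.n_molecules() == 2
        _, log2 = eng.step(state, kin, MutationParams(), offspring_offset=1.0)
        assert log2.replications == 1
        mols = state.free_molecules()
        assert len(mols) == 3
        assert all(m.species == REPLICASE for m in mols)

    def test_fully_folded_world_decays_to_extinction(self):
        """With l = 1 everywhere, omega = 0: no complex ever forms and the
        population reaches zero no later than the largest initial rlt."""
        kin = KineticParams(d=0.5)
        state = make_world(kin, seed=9)
        rng = make_state(77)
        from rpsim._rng import open_uniform
        max_rlt = 0.0
        for i in range(40):
            rlt = -math.log(open_uniform(rng)) / kin.d
            max_rlt = max(max_rlt, rlt)
            state.add_molecule(REPLICASE if i % 2 else PARASITE,
                               (i * 1.3) % 32, (i * 2.1) % 32, 0.9, 1.0, rlt)
        counts = [state.n_molecules()]
        logs = step_n(state, kin, int(max_rlt) + 2)
        assert state.n_molecules() == 0
        assert all(l.complex_formations == 0 for l in logs)

    def test_replication_race_preempted_by_dissociation(self):
        """A complex whose dissociation clock expires dissociates without
        replicating, even though its replication clock is also overdue."""
        kin = KineticParams(d=0.0, D=0.0, D_complex=0.0)
        state = make_world(kin, decay_mode="frozen")
        state.add_complex(PARASITE, 5.0, 5.0, 0.55, 0.2, K.INF,
                          0.7, 0.0, K.INF, ttr=1e-5, dissociation_rlt=0.5)
        _, log = eng.step(state, kin, MutationParams())
        assert log.dissociations == 1
        assert log.replications == 0
        assert len(state.free_molecules()) == 2


class TestFrozenClocks:
    def test_frozen_mode_restores_stored_lifetimes(self):
        kin = KineticParams(d=0.1, D=0.0, D_complex=0.0)
        state = make_world(kin, decay_mode="frozen")
        state.add_complex(PARASITE, 5.0, 5.0, 0.55, 0.2, 7.25,
                          0.7, 0.0, 9.5, ttr=K.INF, dissociation_rlt=3.0)
        step_n(state, kin, 3)   # dissociation fires at step 3
        mols = {m.species: m for m in state.free_molecules()}
        assert mols[REPLICASE].rlt == pytest.approx(9.5)
        assert mols[PARASITE].rlt == pytest.approx(7.25)

    def test_ticking_mode_decays_complexed_members(self):
        """In ticking mode a component expiring mid-complex dies and frees
        its partner with its remaining clock."""
        kin = KineticParams(d=0.1, D=0.0, D_complex=0.0)
        state = make_world(kin, decay_mode="ticking")
        state.add_complex(PARASITE, 5.0, 5.0, 0.55, 0.2, 2.5,
                          0.7, 0.0, 20.0, ttr=K.INF, dissociation_rlt=K.INF)
        for _ in range(2):
            _, log = eng.step(state, kin, MutationParams())
            assert log.decays_in_complex == 0
        _, log = eng.step(state, kin, MutationParams())
        assert log.decays_in_complex == 1   # template clock 2.5 hits 0 at step 3
        mols = state.free_molecules()
        assert len(mols) == 1
        assert mols[0].species == REPLICASE
        # catalyst clock also ticked three times inside the complex
        assert mols[0].rlt == pytest.approx(17.0)

    def test_dissociation_positions_components_together(self):
        kin = KineticParams(d=0.0, D=0.0, D_complex=0.0)
        state = make_world(kin, decay_mode="frozen")
        state.add_complex(PARASITE, 3.0, 4.0, 0.55, 0.2, K.INF,
                          0.7, 0.0, K.INF, ttr=K.INF, dissociation_rlt=1.0)
        eng.step(state, kin, MutationParams())
        mols = state.free_molecules()
        assert len(mols) == 2
        assert all((m.x, m.y) == (3.0, 4.0) for m in mols)


class TestConservationAndBounds:
    def test_ledger_balances_over_a_run(self):
        """Delta(total molecules) per step equals replications - decays -
        crowding removals; formation/dissociation conserve."""
        cfg = small_config(max_steps=400)
        cfg.mutation = MutationParams(mu_a=0.05, mu_l=0.05,
                                      mutate_a_parasite=True,
                                      mutate_l_parasite=True)
        deltas = []

        last_total = [None]

        def audit(state, log):
            total = state.n_molecules()
            if log is not None:
                change = total - last_total[0]
                expected = (log.replications - log.decays_free
                            - log.decays_in_complex - log.overcrowd_molecules)
                assert change == expected
            last_total[0] = total

        res = rpsim.run(cfg, observers=[audit])
        assert res.final_step > 0

    def test_attribute_bounds_hold_throughout(self):
        cfg = small_config(max_steps=600, seed=11)
        cfg.mutation = MutationParams(mu_a=0.3, mu_l=0.3, delta=0.2,
                                      mutate_a_parasite=True,
                                      mutate_l_parasite=True,
                                      mutate_a_replicase=True,
                                      mutate_l_replicase=True)

        def check(state, log):
            n = state.n_top
            live = state.alive[:n] == 1
            for col in (K.F_A, K.F_L):
                vals = state.ent[:n, col][live]
                if vals.size:
                    assert vals.min() >= 0.0 and vals.max() <= 1.0

        rpsim.run(cfg, observers=[check])

    def test_species_never_change_and_catalysts_are_replicases(self):
        cfg = small_config(max_steps=300, seed=13)

        def check(state, log):
            for c in state.complexes():
                assert c.catalyst.species == REPLICASE

        res = rpsim.run(cfg, observers=[check])
        # ids are never reused within a run
        ids = [m.id for m in res.final_state.free_molecules()]
        assert len(ids) == len(set(ids))

    def test_crowding_cap_enforced(self):
        """An entity seeing more than n_max neighbors on its turn is
        removed."""
        kin = KineticParams(d=0.0, D=0.0, D_complex=0.0, n_max=3)
        state = make_world(kin, seed=21)
        # 6 mutually overlapping molecules, l=1 so no complexes form
        for i in range(6):
            state.add_molecule(REPLICASE, 5.0 + 0.01 * i, 5.0, 0.7, 1.0, K.INF)
        _, log = eng.step(state, kin, MutationParams())
        assert log.overcrowd_removals >= 1
        # processing in random order removes agents until survivors see <= 3
        assert state.n_molecules() <= 4


class TestDeterminism:
    def test_identical_seed_identical_series(self):
        cfg = small_config(max_steps=150, seed=42)
        r1 = rpsim.run(cfg)
        r2 = rpsim.run(cfg)
        assert r1.outcome == r2.outcome
        assert r1.timeseries.equals(r2.timeseries)

    def test_observers_do_not_perturb_the_run(self):
        cfg = small_config(max_steps=150, seed=42)
        r1 = rpsim.run(cfg)
        seen = []
        r2 = rpsim.run(cfg, observers=[lambda s, l: seen.append(s.step_count)])
        assert len(seen) > 1
        assert r1.timeseries.equals(r2.timeseries)

    def test_different_seeds_differ(self):
        cfg = small_config(max_steps=150, seed=1)
        r1 = rpsim.run(cfg)
        cfg.seed = 2
        r2 = rpsim.run(cfg)
        assert not r1.timeseries.equals(r2.timeseries)


class TestObjectLevelRules:
    def _mol(self, species, a, l, x=1.0, y=1.0, rlt=10.0, mid=0):
        return Molecule(id=mid, species=species, x=x, y=y, a=a, l=l, rlt=rlt)

    def test_parasite_is_always_template(self, kin_default, rng):
        r = self._mol(REPLICASE, 0.7, 0.0)
        p = self._mol(PARASITE, 0.55, 0.2, x=1.5)
        # replicase initiates on parasite
        for _ in range(50):
            c = attempt_complex_formation(r, p, kin_default, rng)
            if c is not None:
                assert c.template.species == PARASITE
                assert c.catalyst.species == REPLICASE
                break
        else:
            pytest.fail("no complex formed in 50 attempts at omega=0.44")
        # parasite initiates on replicase: the parasite is still the template
        c = None
        for _ in range(50):
            c = attempt_complex_formation(p, r, kin_default, rng)
            if c is not None:
                break
        assert c.template.species == PARASITE

    def test_non_initiator_is_template_between_replicases(self, kin_default, rng):
        x = self._mol(REPLICASE, 0.7, 0.0, mid=1)
        n = self._mol(REPLICASE, 0.9, 0.0, x=1.5, mid=2)
        for _ in range(50):
            c = attempt_complex_formation(x, n, kin_default, rng)
            if c is not None:
                assert c.template.id == 2
                break
        else:
            pytest.fail("no complex formed")

    def test_parasite_pair_rejected(self, kin_default, rng):
        p1 = self._mol(PARASITE, 0.5, 0.0)
        p2 = self._mol(PARASITE, 0.5, 0.0, x=1.5)
        with pytest.raises(ValueError):
            attempt_complex_formation(p1, p2, kin_default, rng)

    def test_full_affinity_never_dissociates(self, kin_default, rng):
        r = self._mol(REPLICASE, 0.7, 0.0)
        t = self._mol(REPLICASE, 1.0, 0.0, x=1.5)
        for _ in range(20):
            c = attempt_complex_formation(r, t, kin_default, rng)
            if c is not None:
                assert c.dissociation_rlt >= 1e200
                return

    def test_replicate_copies_template_without_mutation(self, kin_default, rng):
        r = self._mol(REPLICASE, 0.7, 0.0)
        p = self._mol(PARASITE, 0.55, 0.2, x=1.5)
        c = None
        while c is None:
            c = attempt_complex_formation(r, p, kin_default, rng)
        c.ttr = 0.0
        off, cat, tpl = eng.replicate(c, kin_default, MutationParams(), rng)
        assert off.species == PARASITE
        assert (off.a, off.l) == (0.55, 0.2)
        assert cat.species == REPLICASE and tpl.species == PARASITE


class TestRunLoop:
    def test_no_event_world_survives_step_limit(self):
        """Decay off and omega = 0: every count stays constant to the end."""
        cfg = small_config(max_steps=100, l_P0=1.0, l_R0=1.0)
        cfg.kinetics = KineticParams(d=0.0)
        res = rpsim.run(cfg)
        assert res.outcome == "survived"
        assert res.final_step == 100
        ts = res.timeseries
        assert (ts["n_R_total"] == 60).all()
        assert (ts["n_P_total"] == 60).all()

    def test_step_limit_validation(self):
        cfg = small_config(max_steps=0)
        with pytest.raises(ValueError):
            rpsim.run(cfg)
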