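import numpy as np
import pytest

import ribotraffic as rt
from ribotraffic.core import MRNASpecies, TranslationSystem
from ribotraffic.simulate import apply_event, enabled_events, init_state, step
from ribotraffic.synthetic import make_oracle_instance, state_key


def two_species_system(**over):
    kw = dict(
        mrnas=[MRNASpecies("m", np.array([1, 2, 1, 2, 1, 2]), 1)],
        T=[5, 7], V=[2.0, 2.0], K=[1.0, 1.0], kappa=1.0, alpha=0.5, beta=10.0,
        w=2, labels=["t1", "t2"],
    )
    kw.update(over)
    return TranslationSystem(**kw)


class TestInitState:
    def test_empty_lattices_and_full_charging(self):
        system = two_species_system()
        st0 = init_state(system)
        assert st0.n_ribosomes() == 0
        assert st0.a.tolist() == [5, 7] and st0.b.tolist() == [0, 0]
        assert st0.t == 0.0
        st0.check_invariants(system)


class TestEnabledEvents:
    def test_empty_lattices_enable_one_initiation_per_copy(self):
        system = two_species_system(
            mrnas=[MRNASpecies("m", np.array([1, 2, 1, 2, 1, 2]), 4)]
        )
        cat = enabled_events(system, init_state(system))
        kinds = [e.kind for e in cat.events]
        assert kinds.count("init") == 4
        assert cat.total_rate == pytest.approx(4 * system.alpha)

    def test_single_ribosome_with_clear_road_hops_at_kappa_a(self):
        system = two_species_system(alpha=0.0)
        st0 = init_state(system)
        st0.positions[0] = [3]
        cat = enabled_events(system, st0)
        (ev,) = [e for e in cat.events if e.kind == "elong"]
        assert ev.rate == pytest.approx(system.kappa * st0.a[0])  # codon 3 is species 1

    def test_trailing_ribosome_behind_a_w_gap_is_excluded(self):
        system = two_species_system(alpha=0.0)
        st0 = init_state(system)
        st0.positions[0] = [4, 2]  # gap w exactly: reader at 2 may not move to 3
        cat = enabled_events(system, st0)
        movers = [(e.lattice, e.rib) for e in cat.events if e.kind == "elong"]
        assert (0, 1) not in movers
        assert (0, 0) in movers

    def test_entry_blocked_while_reader_within_w_of_start(self):
        system = two_species_system()
        st0 = init_state(system)
        st0.positions[0] = [2]
        assert not any(e.kind == "init" for e in enabled_events(system, st0).events)
        st0.positions[0] = [3]
        assert any(e.kind == "init" for e in enabled_events(system, st0).events)

    def test_starved_codon_cannot_elongate(self):
        system = two_species_system(alpha=0.0)
        st0 = init_state(system)
        st0.positions[0] = [2]  # codon 2 is species 2
        st0.a[1] = 0
        st0.b[1] = 7
        assert not any(e.kind == "elong" for e in enabled_events(system, st0).events)


class TestStep:
    def test_waiting_times_are_exponential_with_the_total_rate(self):
        system = two_species_system(alpha=0.7)
        rng = np.random.default_rng(0)
        draws = []
        for _ in range(4000):
            st0 = init_state(system)  # only initiation events, rate = 0.7
            _, dt = step(system, st0, rng)
            draws.append(dt)
        mean = np.mean(draws)
        se = np.std(draws, ddof=1) / np.sqrt(len(draws))
        assert abs(mean - 1 / 0.7) < 3 * se

    def test_elongation_moves_one_charged_trna_to_the_bare_pool(self):
        system = two_species_system(alpha=0.0)
        st0 = init_state(system)
        st0.positions[0] = [2]
        cat = enabled_events(system, st0)
        (ev,) = [e for e in cat.events if e.kind == "elong"]
        apply_event(system, st0, ev)
        assert st0.a.tolist() == [5, 6] and st0.b.tolist() == [0, 1]
        st0.check_invariants(system)

    def test_invariants_hold_along_a_trajectory(self):
        system = two_species_system(alpha=0.9)
        rng = np.random.default_rng(3)
        st0 = init_state(system)
        for i in range(5000):
            step(system, st0, rng)
            if i % 50 == 0:
                st0.check_invariants(system)

    def test_empirical_occupancy_matches_exact_stationary_distribution(self):
        """Time-weighted state occupancy of the 8-state micro-system agrees
        with the enumerated CTMC solution within total variation 0.02."""
        system, sol = make_oracle_instance("two_site_pool")
        rng = np.random.default_rng(12)
        st0 = init_state(system)
        for _ in range(20000):
            step(system, st0, rng)
        dwell = {}
        total = 0.0
        for _ in range(250000):
            key = state_key(st0.positions, st0.a)
            _, dt = step(system, st0, rng)
            dwell[key] = dwell.get(key, 0.0) + dt
            total += dt
        tv = 0.5 * sum(
            abs(dwell.get(k, 0.0) / total - float(p)) for k, p in zip(sol.states, sol.pi)
        )
        tv += 0.5 * sum(v / total for k, v in dwell.items() if k not in sol.index)
        assert tv < 0.02


class TestRun:
    def test_alpha_zero_gives_empty_steady_state(self, mono):
        system = mono(L=30, m=3, alpha=0.0)
        obs = rt.run(system, rt.Schedule(2, 20), seed=1)
        assert np.all(obs.J == 0)
        assert all(np.all(p == 0) for p in obs.reader_profiles.values())
        assert np.allclose(obs.c, 1.0)

    def test_same_seed_reproduces_the_observable_set(self, mono):
        system = mono(L=60, m=5, alpha=0.05)
        o1 = rt.run(system, rt.Schedule(10, 50), seed=7)
        o2 = rt.run(system, rt.Schedule(10, 50), seed=7)
        assert np.array_equal(o1.J, o2.J)
        assert np.array_equal(o1.c, o2.c)
        for name in o1.reader_profiles:
            assert np.array_equal(o1.reader_profiles[name], o2.reader_profiles[name])
        o3 = rt.run(system, rt.Schedule(10, 50), seed=8)
        assert not np.array_equal(o1.blocks["term"], o3.blocks["term"])

    @pytest.mark.parametrize("preset", ["l6_two_species", "l12_fixed", "two_copies_pool"])
    def test_current_matches_exact_ctmc_oracle(self, preset):
        """Independent replicas agree with the enumerated stationary
        solution within three standard errors of the replica mean."""
        system, sol = make_oracle_instance(preset)
        runs = [rt.run(system, rt.Schedule(200, 5000), seed=600 + i) for i in range(4)]
        name = system.mrnas[0].name
        J = np.array([o.J[0] for o in runs])
        sem = J.std(ddof=1) / 2
        assert abs(J.mean() - sol.J[0]) < 3 * max(sem, 1e-4)
        rho = np.mean([o.reader_profiles[name] for o in runs], axis=0)
        assert np.allclose(rho, sol.rho[name], atol=0.02)
        c = np.mean([o.c for o in runs], axis=0)
        assert np.allclose(c, sol.c, atol=0.02)

    def test_final_state_respects_conservation_and_exclusion(self, mrna_a_system):
        obs = rt.run(mrna_a_system, rt.Schedule(30, 60), seed=3)
        fin = obs.blocks["final_state"]
        assert np.array_equal(fin["a"] + fin["b"], mrna_a_system.T)
        for ps in fin["positions"]:
            gaps = np.diff(sorted(ps))
            assert np.all(gaps >= mrna_a_system.w)

    def test_flux_is_conserved_along_the_lattice(self, mono):
        system = mono(L=80, m=10, alpha=0.03, V=300.0, T_tot=2000)
        obs = rt.run(system, rt.Schedule(100, 800), seed=9)
        flux = obs.flux_profiles["uniform"]
        se = obs.flux_se_profiles["uniform"]
        i, j = 10, 70
        assert abs(flux[i] - flux[j]) < 3 * (se[i] + se[j])
        # J equals the mid-ORF hop rate
        mid = 40
        assert abs(obs.J[0] - flux[mid]) < 3 * (obs.J_se[0] + se[mid])

    def test_infinite_recharge_flag_equals_a_huge_recharging_rate(self, mono):
        fast = mono(L=60, m=8, alpha=0.3, V=1e9, K=1.0, T_tot=1000)
        inf = mono(L=60, m=8, alpha=0.3, T_tot=1000, infinite_recharge=True)
        o1 = rt.run(fast, rt.Schedule(50, 400), seed=11)
        o2 = rt.run(inf, rt.Schedule(50, 400), seed=12)
        assert abs(o1.J[0] - o2.J[0]) < 3 * (o1.J_se[0] + o2.J_se[0])
        assert np.allclose(o1.c, 1.0, atol=1e-3)

    def test_measure_time_must_be_positive(self):
        with pytest.raises(ValueError):
            rt.Schedule(1.0, 0.0)
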