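import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ribotraffic as rt
from ribotraffic.analytics import (
    alpha_star,
    cai,
    classify_designer_regime,
    critical_alphas,
    ld_alpha_for_current,
    ld_boundary,
    ld_theory,
    qli,
    qp_threshold,
    rscu_weights,
    supply_demand,
)
from ribotraffic.core import MRNASpecies, TranslationSystem


def simple_system(codons_per_mrna, T, copies=None, V=None, kappa=0.01, alpha=0.1):
    codons_per_mrna = [np.asarray(c) for c in codons_per_mrna]
    copies = copies or [1] * len(codons_per_mrna)
    S = len(T)
    mrnas = [
        MRNASpecies(f"m{i}", c, m) for i, (c, m) in enumerate(zip(codons_per_mrna, copies))
    ]
    V = V if V is not None else [50.0] * S
    return TranslationSystem(
        mrnas=mrnas, T=T, V=V, K=[3.0] * S, kappa=kappa, alpha=alpha, beta=100.0,
        w=3, labels=[f"t{i+1}" for i in range(S)],
    )


class TestSupplyDemand:
    def test_equal_pools_give_uniform_supply(self):
        system = simple_system([[1, 2, 3]], T=[50, 50, 50])
        sigma, f, Q = supply_demand(system)
        assert np.allclose(sigma, 1 / 3)

    def test_mono_codon_demand_concentrates_on_one_species(self):
        system = simple_system([[2] * 10], T=[40, 60])
        sigma, f, Q = supply_demand(system)
        assert f.tolist() == [0.0, 1.0]

    def test_matched_supply_and_demand_gives_unit_ratio(self):
        system = simple_system([[1] * 2 + [2] * 3], T=[40, 60])
        sigma, f, Q = supply_demand(system)
        assert np.allclose(Q, 1.0)

    def test_normalisation_and_permutation_invariance(self):
        rng = np.random.default_rng(0)
        codons = rng.integers(1, 4, size=60)
        s1 = simple_system([codons], T=[30, 40, 50])
        s2 = simple_system([rng.permutation(codons)], T=[30, 40, 50])
        for a, b in zip(supply_demand(s1), supply_demand(s2)):
            assert np.allclose(a, b)
        sigma, f, _ = supply_demand(s1)
        assert sigma.sum() == pytest.approx(1.0)
        assert f.sum() == pytest.approx(1.0)


class TestLDTheory:
    def test_dilute_limit_every_initiation_succeeds(self):
        for alpha in (1e-6, 1e-4):
            assert ld_theory(alpha, 10.0, 9).J == pytest.approx(alpha, rel=1e-3)

    @given(st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_current_increases_with_initiation_on_the_ld_domain(self, frac):
        k, w = 10.0, 9
        amax = ld_boundary(k, w)
        a1, a2 = frac * amax * 0.99, min(frac * amax * 0.99 + 1e-3, amax)
        assert ld_theory(a2, k, w).J >= ld_theory(a1, k, w).J

    def test_inverse_solves_the_forward_formula(self):
        k, w = 8.0, 9
        for alpha in (0.1, 0.5, 1.0):
            C = ld_theory(alpha, k, w).J
            assert ld_alpha_for_current(C, k, w) == pytest.approx(alpha, rel=1e-9)

    def test_out_of_domain_is_flagged_and_unreachable_current_is_inf(self):
        assert not ld_theory(5.0, 10.0, 9).in_ld_domain
        assert ld_alpha_for_current(10.0, 10.0, 9) == np.inf

    def test_matches_high_precision_simulation_at_a_tenth_of_k(self, mono):
        """alpha = 0.1 k on a uniform lattice: closed form within 2%."""
        k, w = 10.0, 9
        system = mono(L=60, m=10, alpha=0.1 * k, T_tot=2000, infinite_recharge=True)
        obs = rt.run(system, rt.Schedule(100, 2500), seed=17)
        th = ld_theory(0.1 * k, k, w)
        assert obs.J[0] == pytest.approx(th.J, rel=0.02)
        inner = slice(w, 60 - w)
        assert obs.reader_profiles["uniform"][inner].mean() == pytest.approx(th.rho, rel=0.04)


class TestCriticalAlphas:
    def test_largest_q_species_is_the_predicted_bottleneck(self):
        # Q = (2, 1, 0.5) with equal recharging capacity
        codons = [1] * 20 + [2] * 10 + [3] * 5
        T_tot = 300
        system = simple_system(
            [codons], T=[int(T_tot * 10 / 35), int(T_tot * 10 / 35), int(T_tot * 15 / 35)],
            V=[0.5, 0.5, 0.5],
        )
        res = critical_alphas(system)
        assert res.bottleneck_index == 0
        order_q = np.argsort(-res.Q)
        order_a = np.argsort(res.alpha_c_first_order)
        assert np.array_equal(order_q, order_a)

    def test_doubling_copy_numbers_halves_alpha_c_to_first_order(self):
        codons = [[1] * 6 + [2] * 3]
        s1 = simple_system(codons, T=[200, 100], copies=[5])
        s2 = simple_system(codons, T=[200, 100], copies=[10])
        r1, r2 = critical_alphas(s1), critical_alphas(s2)
        assert np.allclose(r2.alpha_c_first_order, r1.alpha_c_first_order / 2)

    def test_mono_codon_alpha_c_coincides_with_alpha_star(self):
        system = simple_system([[1] * 40], T=[500], copies=[10], V=[30.0], kappa=0.02)
        res = critical_alphas(system)
        k = system.kappa * system.T[0]
        assert res.alpha_star == pytest.approx(
            alpha_star(k, 30.0, system.n_codons_total, system.w)
        )
        assert res.alpha_c[0] == pytest.approx(res.alpha_star, rel=1e-9)

    def test_unreachable_species_are_reported_as_non_bottlenecks(self):
        system = simple_system([[1] * 10 + [2]], T=[100, 100], V=[1e7, 1e7])
        res = critical_alphas(system)
        assert not np.isfinite(res.alpha_c).any()
        assert res.bottleneck_index is None


class TestQPThreshold:
    def test_threshold_increases_with_the_slow_site_rate(self):
        k, w = 10.0, 9
        qs = np.linspace(0.5, 10.0, 25)
        vals = [qp_threshold(q, k, w) for q in qs]
        assert np.all(np.diff(vals) > 0)

    def test_equal_rates_reduce_to_the_ld_boundary(self):
        k, w = 10.0, 9
        assert qp_threshold(k, k, w) == pytest.approx(ld_boundary(k, w), rel=1e-6)

    def test_fast_center_is_not_a_bottleneck(self):
        assert qp_threshold(12.0, 10.0, 9) == np.inf


class TestDesignerRegimes:
    @pytest.mark.parametrize(
        "preset,region",
        [("lr1", "LR1_queueing"), ("qp", "QP"), ("lr2", "LR2_no_queueing")],
    )
    def test_presets_classify_into_the_three_regions(self, preset, region):
        from ribotraffic.synthetic import designer_preset

        system, _ = designer_preset(preset)
        assert classify_designer_regime(system).region == region


class TestCodonUsageIndices:
    def test_rscu_two_codon_family_hand_computation(self):
        # counts (30, 10): RSCU = (1.5, 0.5), weights (1, 1/3)
        counts = {"GAA": 30, "GAG": 10}
        rscu, weights = rscu_weights(counts)
        assert rscu["GAA"] == pytest.approx(1.5)
        assert rscu["GAG"] == pytest.approx(0.5)
        assert weights["GAA"] == pytest.approx(1.0)
        assert weights["GAG"] == pytest.approx(1 / 3)

    def test_gene_of_maximal_weight_codons_has_cai_one(self):
        counts = {"GAA": 30, "GAG": 10, "AAA": 5, "AAG": 20}
        _, weights = rscu_weights(counts)
        assert cai(["GAA", "AAG", "GAA"], weights) == pytest.approx(1.0)

    def test_uniform_mrna_qli_equals_its_species_ratio(self):
        Q = np.array([0.5, 2.0, 1.0])
        assert qli(np.full(30, 2), Q) == pytest.approx(2.0)

    def test_qli_is_permutation_invariant(self):
        rng = np.random.default_rng(1)
        ids = rng.integers(1, 4, 50)
        Q = np.array([0.5, 2.0, 1.2])
        assert qli(ids, Q) == pytest.approx(qli(rng.permutation(ids), Q))

    def test_mean_qli_decreases_along_the_bias_sweep(self, table, code):
        """Genes sampled closer to supply-proportional usage have lower
        queueing likelihood."""
        from ribotraffic.synthetic import make_random_gene_set

        biases = np.repeat(np.linspace(0.0, 1.0, 5), 40)
        genes = make_random_gene_set(200, (200, 400), biases, seed=11, table=table, code=code)
        sigma = table.gene_copy_number / table.gene_copy_number.sum()
        counts = np.zeros(table.n_species)
        for g in genes:
            counts += np.bincount(g.ids - 1, minlength=table.n_species)
        Q = (counts / counts.sum()) / sigma
        vals = np.array([qli(g.ids, Q) for g in genes])
        means = [vals[biases == b].mean() for b in np.linspace(0.0, 1.0, 5)]
        assert np.all(np.diff(means) < 0)
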