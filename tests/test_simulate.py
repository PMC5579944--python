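import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import chisquare

from micronmf import (
    MixtureSpec,
    NoiseSpec,
    TypeMatrix,
    build_holling_network,
    cooccurrence_network,
    default_edge_plan,
    mislabel,
    network_components,
    optimal_loss,
    related_class_types,
    simulate_from_types,
    simulate_holling,
    simulate_mixture_classes,
    simulate_zero_inflated,
    subcommunity_loss,
)


class TestNoiseSpec:
    def test_sd_vector_scales_with_snr(self):
        T = related_class_types(30, [3], seed=1)[0]
        sd1 = NoiseSpec.from_types(T, 1).sd_vector
        sd2 = NoiseSpec.from_types(T, 2).sd_vector
        sd4 = NoiseSpec.from_types(T, 4).sd_vector
        np.testing.assert_allclose(sd2, sd1 / 2)
        np.testing.assert_allclose(sd4, sd1 / 4)

    def test_infinite_snr_means_no_noise(self):
        T = related_class_types(10, [2], seed=2)[0]
        spec = NoiseSpec.from_types(T, np.inf)
        assert np.all(spec.sd_vector == 0)
        with pytest.raises(ValueError):
            NoiseSpec(np.inf, np.ones(10))


class TestSimulateFromTypes:
    def test_large_depth_proportions_converge_to_mean(self):
        T = related_class_types(20, [2], seed=3)[0]
        for seed in range(5):
            X, W = simulate_from_types(T, np.full(4, 1e6), seed=seed)
            mean = T.values @ W.values
            props = X.values / X.values.sum(axis=0)
            assert np.abs(props - mean / mean.sum(axis=0)).max() < 0.01

    def test_single_type_counts_are_poisson(self):
        # chi-square goodness of fit of X against depth * T in most reps
        rng = np.random.default_rng(4)
        t = rng.dirichlet(np.ones(10) * 5)
        T = TypeMatrix(t[:, None])
        ok = 0
        for rep in range(100):
            X, _ = simulate_from_types(T, [2000.0], seed=rep)
            # condition on the realized total (Poisson -> multinomial)
            stat, p = chisquare(X.values[:, 0], X.values[:, 0].sum() * t)
            ok += p > 0.01
        assert ok >= 95

    def test_true_weights_match_requested_depths(self):
        T = related_class_types(15, [3], seed=5)[0]
        depths = np.array([100.0, 5000.0, 250.0])
        _, W = simulate_from_types(T, depths, seed=6)
        np.testing.assert_allclose(W.values.sum(axis=0), depths, rtol=1e-12)


class TestSimulateZeroInflated:
    def test_huge_alpha_approaches_equal_weights(self):
        T = related_class_types(10, [4], seed=7)[0]
        _, W = simulate_zero_inflated(T, np.full(50, 1000.0), alpha=1e6, seed=8)
        np.testing.assert_allclose(W.values, 250.0, rtol=0.05)

    def test_tiny_alpha_zeroes_most_weights(self):
        T = related_class_types(12, [6], seed=9)[0]
        _, W = simulate_zero_inflated(T, np.full(2000, 1000.0), alpha=0.005, seed=10)
        frac_tiny = np.mean((W.values / 1000.0) < 1e-6)
        assert frac_tiny > 0.5

    def test_sparser_than_uniform_weights(self):
        T = related_class_types(40, [5], seed=11)[0]
        depths = np.full(60, 2000.0)
        wins, sp_z, sp_u = 0, [], []
        for seed in range(10):
            Xz, _ = simulate_zero_inflated(T, depths, seed=seed)
            Xu, _ = simulate_from_types(T, depths, seed=seed)
            sp_z.append((Xz.values == 0).mean())
            sp_u.append((Xu.values == 0).mean())
            wins += sp_z[-1] > sp_u[-1]
        assert wins >= 8
        assert np.mean(sp_z) > np.mean(sp_u)


class TestMislabel:
    def test_zero_fraction_is_identity(self):
        labels = np.array(["a", "b"] * 5)
        np.testing.assert_array_equal(mislabel(labels, 0.0, seed=1), labels)

    def test_exact_flip_count(self):
        labels = np.array(["a"] * 5 + ["b"] * 5)
        flipped = mislabel(labels, 0.5, seed=2)
        assert int(np.sum(flipped != labels)) == 5

    def test_same_seed_twice_is_involution(self):
        labels = np.array(["x", "y", "y", "x", "y", "x", "x", "y"])
        twice = mislabel(mislabel(labels, 0.25, seed=3), 0.25, seed=3)
        np.testing.assert_array_equal(twice, labels)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            mislabel(np.array(["a", "b", "c"]), 0.1)


class TestSimulateMixtureClasses:
    def _spec(self, s, depth=10000, n=20):
        rng = np.random.default_rng(12)
        p1 = rng.dirichlet(np.ones(30))
        p2 = rng.dirichlet(np.ones(30))
        return MixtureSpec(p1, p2, s, depth=depth, n_per_class=n)

    def test_unit_effect_size_gives_identical_classes(self):
        spec = self._spec(1.0)
        prob_a = (spec.p_base1 + spec.p_base2) / 2
        prob_b = (spec.p_base1 + spec.p_base2) / 2
        np.testing.assert_allclose(prob_a, prob_b)

    def test_column_sums_equal_depth(self):
        X, part = simulate_mixture_classes(self._spec(1.3), seed=13)
        assert np.all(X.depths == 10000)
        assert part.g == 2 and part.n_samples == 40

    def test_large_effect_size_limit(self):
        spec = self._spec(1e9)
        X, part = simulate_mixture_classes(spec, seed=14)
        a = X.values[:, part.indices_of("A")].sum(axis=1)
        b = X.values[:, part.indices_of("B")].sum(axis=1)
        # class A tends to base 2, class B to base 1
        assert np.corrcoef(a, spec.p_base2)[0, 1] > np.corrcoef(a, spec.p_base1)[0, 1]
        assert np.corrcoef(b, spec.p_base1)[0, 1] > np.corrcoef(b, spec.p_base2)[0, 1]

    def test_effect_size_below_one_rejected(self):
        with pytest.raises(ValueError):
            self._spec(0.5)


class TestHollingNetwork:
    def test_interaction_ranges_by_color(self):
        plan = default_edge_plan([(0, 6), (4, 10)], n_blue=4, n_red=3, seed=1)
        system = build_holling_network([(0, 6), (4, 10)], isolated=2,
                                       edge_plan=plan, seed=2)
        for i, j, color in system.edges:
            for s, t in ((i, j), (j, i)):
                b = system.b[s, t]
                if color == "black":
                    assert 0 <= b <= 0.008
                elif color == "blue":
                    assert -0.002 <= b <= 0.008
                else:
                    assert -0.08 <= b <= 0

    def test_handling_time_distribution(self):
        plan = [(i, j, "black") for i in range(24) for j in range(i + 1, 24)]
        draws = []
        for seed in range(20):
            system = build_holling_network([(0, 24)], isolated=0,
                                           edge_plan=plan, seed=seed)
            draws.append(1.0 / system.th[system.th > 0])
        inv_th = np.concatenate(draws)
        assert inv_th.size >= 10_000
        # 1/TH ~ 1e5 * Beta(5,1): mean 1e5 * 5/6
        assert abs(inv_th.mean() - 1e5 * 5 / 6) / (1e5 * 5 / 6) < 0.02

    def test_conflicting_edge_colors_rejected(self):
        with pytest.raises(ValueError, match="assigned both"):
            build_holling_network(
                [(0, 4)], edge_plan=[(0, 1, "black"), (1, 0, "red")], seed=4
            )

    def test_empty_plan_gives_pure_logistic_dynamics(self):
        system = build_holling_network([(0, 3)], isolated=0, edge_plan=[], seed=5)
        assert np.all(system.b == 0)


class TestSimulateHolling:
    def test_logistic_equilibrium_without_interactions(self):
        system = build_holling_network([(0, 2)], isolated=0, edge_plan=[], seed=6)
        X, _ = simulate_holling(
            system, 3, seed=7, n_steps=100_000,
            growth=[1.0, 1.0], self_limit=[0.01, 0.01], m0=[5.0, 150.0],
        )
        np.testing.assert_allclose(X.values, 100.0, rtol=0.001)

    def test_zero_abundance_is_absorbing(self):
        system = build_holling_network(
            [(0, 2)], isolated=0, edge_plan=[(0, 1, "black")], seed=8
        )
        X, _ = simulate_holling(
            system, 2, seed=9, n_steps=5_000,
            growth=[0.9, 0.9], self_limit=[0.01, 0.01], m0=[0.0, 4.0],
        )
        assert np.all(X.values[0] == 0)
        assert np.all(X.values[1] > 0)

    def test_mutualists_exceed_isolated_carrying_capacity(self):
        system = build_holling_network(
            [(0, 2)], isolated=0, edge_plan=[(0, 1, "black")], seed=10
        )
        r, c = 0.5, 0.01
        X, _ = simulate_holling(
            system, 2, seed=11, n_steps=200_000,
            growth=[r, r], self_limit=[c, c], m0=[10.0, 10.0],
        )
        assert np.all(X.values > 1.0 / c)
        # oracle: symmetric-ish fixed point of the 2-D system solved 1-D at a
        # time: r(1 - c m_i) + b a m_j / (1 + a th m_j) = 0
        b01, b10 = system.b[0, 1], system.b[1, 0]
        th01, th10 = system.th[0, 1], system.th[1, 0]
        m = X.values[:, 0].astype(float)
        for _ in range(200):
            m0_new = brentq(
                lambda v: r * (1 - c * v) + b01 * m[1] / (1 + th01 * m[1]),
                1, 1e9,
            )
            m1_new = brentq(
                lambda v: r * (1 - c * v) + b10 * m[0] / (1 + th10 * m[0]),
                1, 1e9,
            )
            m = np.array([m0_new, m1_new])
        np.testing.assert_allclose(X.values[:, 0], m, rtol=0.01)


class TestRecoveryLoss:
    @pytest.mark.parametrize(
        "true, clusters, expected",
        [
            (set(range(1, 11)), [set(range(1, 11))], 0),
            (set(range(1, 11)), [set(range(1, 6)), set(range(6, 11))], 1),
            (set(range(1, 11)), [set(range(1, 10)) | {11}], 2),
            (set(range(1, 11)), [], 10),
        ],
    )
    def test_loss_examples(self, true, clusters, expected):
        assert subcommunity_loss(true, clusters) == expected

    def test_adding_irrelevant_otu_raises_loss_by_one(self):
        true = {1, 2, 3}
        base = [{1, 2, 3}]
        assert subcommunity_loss(true, [{1, 2, 3, 99}]) == \
            subcommunity_loss(true, base) + 1

    def test_optimal_loss_finds_exact_cover(self):
        loss, chosen = optimal_loss({1, 2, 3}, [{1, 2, 3}, {4, 5}])
        assert loss == 0 and chosen == [{1, 2, 3}]

    def test_singleton_family_costs_m_minus_one(self):
        true = set(range(6))
        loss, _ = optimal_loss(true, [{i} for i in true])
        assert loss == 5

    def test_matches_brute_force_on_random_families(self, rng):
        from itertools import combinations

        for _ in range(5):
            true = set(rng.choice(12, size=6, replace=False).tolist())
            family = [
                set(rng.choice(12, size=rng.integers(1, 5), replace=False).tolist())
                for _ in range(6)
            ]
            loss, _ = optimal_loss(true, family)
            best = subcommunity_loss(true, [])
            for r in range(1, 7):
                for combo in combinations(family, r):
                    best = min(best, subcommunity_loss(true, list(combo)))
            assert loss == best

    def test_beam_search_used_beyond_20_candidates(self, rng):
        family = [{int(i)} for i in range(25)]
        with pytest.warns(RuntimeWarning, match="beam"):
            loss, _ = optimal_loss({0, 1, 2}, family)
        assert loss == 2  # three singletons cover everything


class TestCooccurrenceNetwork:
    def test_duplicated_rows_are_a_significant_edge(self, rng):
        base = rng.poisson(20, size=50).astype(float)
        X = np.vstack([base, base, rng.poisson(20, size=(4, 50))])
        X[:, X.sum(axis=0) == 0] = 1
        table = cooccurrence_network(X, n_perm=500, fdr_level=0.05, seed=1)
        pair = table[(table["i"] == 0) & (table["j"] == 1)].iloc[0]
        assert pair["pvalue"] == pytest.approx(1 / 501)
        assert bool(pair["significant"])

    def test_independent_rows_control_fdr(self, rng):
        fracs = []
        for rep in range(10):
            X = rng.poisson(15, size=(8, 40)).astype(float)
            X[:, X.sum(axis=0) == 0] = 1
            table = cooccurrence_network(X, n_perm=200, fdr_level=0.05,
                                         seed=rep)
            fracs.append(table["significant"].mean())
        assert np.mean(fracs) <= 0.05

    def test_fixed_seed_is_reproducible(self, rng):
        X = rng.poisson(10, size=(5, 30)).astype(float) + 1
        t1 = cooccurrence_network(X, n_perm=100, seed=7)
        t2 = cooccurrence_network(X, n_perm=100, seed=7)
        np.testing.assert_array_equal(t1["pvalue"], t2["pvalue"])

    def test_constant_rows_skipped_with_p_one(self):
        X = np.vstack([np.full(30, 5.0), np.arange(30, dtype=float) + 1])
        table = cooccurrence_network(X, n_perm=100, seed=8)
        assert table["pvalue"].iloc[0] == 1.0

    def test_components_extracted_at_level(self, rng):
        base = rng.poisson(30, size=40).astype(float)
        X = np.vstack([base, base + rng.poisson(2, size=40),
                       rng.poisson(30, size=(3, 40))])
        X[:, X.sum(axis=0) == 0] = 1
        table = cooccurrence_network(X, n_perm=400, seed=9)
        comps = network_components(table, level=0.05)
        assert any({0, 1} <= c for c in comps)
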