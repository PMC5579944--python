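import numpy as np
import pytest

from micronmf import (
    CountMatrix,
    TypeMatrix,
    fit_weights,
    poisson_deviance,
    transform_samples,
)


def _grid_search_2d(T, x, w_max=20.0, step=0.01):
    """Dense 2-D grid maximization of the Poisson log-likelihood (oracle)."""
    grid = np.arange(0.0, w_max + step / 2, step)
    W1, W2 = np.meshgrid(grid, grid, indexing="ij")
    mu1 = T[0, 0] * W1 + T[0, 1] * W2
    mu2 = T[1, 0] * W1 + T[1, 1] * W2
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(x[0] > 0, x[0] * np.log(mu1), 0.0) - mu1 \
            + np.where(x[1] > 0, x[1] * np.log(mu2), 0.0) - mu2
    ll[np.isnan(ll)] = -np.inf
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return np.array([grid[i], grid[j]])


class TestFitWeights:
    def test_k1_weight_equals_depth(self, rng):
        # score equation sum(x_i)/w - sum(t_i) = 0 forces w = depth
        for _ in range(5):
            t = rng.dirichlet(np.ones(6))
            x = rng.poisson(200 * t).astype(float)
            if x.sum() == 0:
                continue
            res = fit_weights(t[:, None], x)
            assert res.weights[0] == pytest.approx(x.sum(), rel=1e-8)

    def test_saturated_identity_fit(self):
        res = fit_weights(np.eye(2), np.array([5.0, 7.0]))
        np.testing.assert_allclose(res.weights, [5.0, 7.0], rtol=1e-8)
        expected = 5 * np.log(5) - 5 + 7 * np.log(7) - 7
        assert res.loglik == pytest.approx(expected, rel=1e-10)

    def test_boundary_optimum_matches_grid_search(self):
        T = np.array([[0.8, 0.2], [0.2, 0.8]])
        x = np.array([10.0, 0.0])
        res = fit_weights(T, x)
        oracle = _grid_search_2d(T, x)
        np.testing.assert_allclose(res.weights, oracle, atol=0.02)
        np.testing.assert_allclose(res.weights, [10.0, 0.0], atol=1e-6)

    def test_random_instances_match_grid_search(self, rng):
        for _ in range(5):
            cols = rng.dirichlet(np.ones(2), size=2).T
            x = rng.poisson(8.0, size=2).astype(float)
            if x.sum() == 0:
                continue
            res = fit_weights(cols, x)
            oracle = _grid_search_2d(cols, x, w_max=30.0)
            mu_fit = cols @ res.weights
            mu_oracle = cols @ oracle
            ll_fit = np.sum(np.where(x > 0, x * np.log(mu_fit + 1e-300), 0) - mu_fit)
            ll_or = np.sum(np.where(x > 0, x * np.log(mu_oracle + 1e-300), 0) - mu_oracle)
            assert ll_fit >= ll_or - 1e-3

    def test_depth_conservation_and_ascent(self, rng):
        T = rng.dirichlet(np.ones(12), size=4).T  # 12 x 4, unit columns
        x = rng.poisson(50 * rng.dirichlet(np.ones(12))).astype(float)
        x[0] += 1
        res = fit_weights(T, x)
        assert res.weights.sum() == pytest.approx(x.sum(), rel=1e-6)
        assert np.all(np.diff(res.loglik_trace) > 0) or res.loglik_trace.size == 1

    def test_kkt_epsilon_move_never_improves(self, rng):
        # at the returned optimum, re-adding any zero-weight type at weight
        # eps (with depth rescale) must not increase the likelihood
        eps = 1e-7
        checked = 0
        for trial in range(200):
            k = int(rng.integers(2, 6))
            p = int(rng.integers(4, 12))
            T = rng.dirichlet(np.ones(p), size=k).T
            x = rng.poisson(30 * rng.dirichlet(np.ones(p) * 0.5)).astype(float)
            if x.sum() == 0:
                continue
            res = fit_weights(T, x, epsilon=eps)
            zeros = [i for i in range(k) if i not in set(res.active_set.tolist())]
            for v in zeros:
                active = list(res.active_set)
                w_trial = np.append(res.weights[active] * (1 - eps), eps)
                w_trial *= x.sum() / w_trial.sum()
                mu = T[:, active + [v]] @ w_trial
                ll = np.sum(np.where(x > 0, x * np.log(np.maximum(mu, 1e-12)), 0) - mu)
                assert ll <= res.loglik + 1e-9
                checked += 1
        assert checked > 20  # the sweep must actually exercise zero weights

    def test_outer_loop_terminates_quickly(self, rng):
        for _ in range(20):
            k = 10
            T = rng.dirichlet(np.ones(15), size=k).T
            x = rng.poisson(40 * rng.dirichlet(np.ones(15))).astype(float)
            if x.sum() == 0:
                continue
            res = fit_weights(T, x)
            assert res.n_outer_iter <= 2**k
            assert res.n_outer_iter <= 25  # far less in practice

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all zeros"):
            fit_weights(np.eye(2), np.zeros(2))


class TestPoissonDeviance:
    def test_saturated_is_zero(self, rng):
        x = rng.poisson(5, size=6).astype(float)
        assert poisson_deviance(x, np.maximum(x, 1e-12)) == pytest.approx(0, abs=1e-9)

    @pytest.mark.parametrize(
        "x, mu, expected",
        [
            ([2], [1], 2 * (2 * np.log(2) - 1)),
            ([0, 4], [1, 2], 2 + 8 * np.log(2) - 4),
        ],
    )
    def test_closed_forms(self, x, mu, expected):
        assert poisson_deviance(x, mu) == pytest.approx(expected, rel=1e-12)

    def test_zero_mean_against_count_is_inf(self):
        assert poisson_deviance([1, 0], [0, 1]) == np.inf

    def test_matches_loglik_gap_to_saturated(self, rng):
        x = rng.poisson(6, size=8).astype(float)
        mu = rng.uniform(1, 10, size=8)
        pos = x > 0
        ll = np.sum(x[pos] * np.log(mu[pos])) - mu.sum()
        ll_sat = np.sum(x[pos] * np.log(x[pos])) - x.sum()
        assert poisson_deviance(x, mu) == pytest.approx(2 * (ll_sat - ll), rel=1e-10)


class TestTransformSamples:
    def test_exact_depth_scaled_types_give_diagonal_weights(self, block_types):
        depths = [100.0, 200.0]
        X = CountMatrix(np.round(block_types.values * depths))
        W, dev = transform_samples(block_types, X)
        np.testing.assert_allclose(np.diag(W.values), depths, rtol=1e-6)
        np.testing.assert_allclose(W.values - np.diag(np.diag(W.values)), 0, atol=1e-4)
        np.testing.assert_allclose(dev, 0, atol=1e-6)

    def test_column_permutation_equivariance(self, rng, block_types):
        W0 = rng.uniform(20, 80, size=(2, 5))
        X = CountMatrix(rng.poisson(block_types.values @ W0).astype(float) + 1)
        perm = [3, 0, 4, 1, 2]
        W_a, dev_a = transform_samples(block_types, X)
        W_b, dev_b = transform_samples(block_types, X.select_samples(perm))
        np.testing.assert_allclose(W_b.values, W_a.values[:, perm], rtol=1e-8)
        np.testing.assert_allclose(dev_b, dev_a[perm], rtol=1e-8)

    def test_mixture_recovery_coverage(self, rng):
        # known mixture at depth 1e5: recovered proportions within 3 SE
        # in the vast majority of repetitions
        T = np.zeros((6, 2))
        T[:4, 0] = [0.4, 0.3, 0.2, 0.1]
        T[2:, 1] = [0.1, 0.2, 0.3, 0.4]
        true_w = np.array([0.3, 0.7]) * 1e5
        hits = 0
        n_rep = 100
        for i in range(n_rep):
            x = rng.poisson(T @ true_w).astype(float)
            res = fit_weights(T, x)
            # Fisher information for the mixing weights
            mu = T @ true_w
            info = T.T @ (T / mu[:, None])
            se = np.sqrt(np.diag(np.linalg.inv(info)))
            hits += np.all(np.abs(res.weights - true_w) <= 3 * se)
        assert hits >= 95

    def test_feature_mismatch_reports_ids(self, block_types):
        X = CountMatrix(np.ones((6, 2)), feature_ids=[f"x{i}" for i in range(6)])
        with pytest.raises(ValueError, match="x0"):
            transform_samples(block_types, X)
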