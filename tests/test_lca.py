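"""The mixed-indicator latent class model: densities, EM steps, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from peerlca import lca
from peerlca.lca import (LcaParameters, ModelSpec, count_parameters, e_step,
                         fit, log_class_density, m_step, simulate_from_params)

HSET = settings(max_examples=25, deadline=None, derandomize=True)


def toy_params(k=2, nc=2, nb=1, shared_cov=0.0, seed=0):
    rng = np.random.default_rng(seed)
    return LcaParameters(
        mixing=np.full(k, 1 / k),
        means=rng.uniform(0.2, 0.8, (k, nc)),
        variances=rng.uniform(0.01, 0.05, (k, nc)),
        shared_cov=shared_cov,
        probs=rng.uniform(0.2, 0.8, (k, nb)) if nb else np.empty((k, 0)))


class TestCountParameters:
    @pytest.mark.parametrize("k,expected", [(5, 105), (1, 21), (2, 42)])
    def test_default_structure(self, k, expected):
        assert count_parameters(ModelSpec(k)) == expected

    def test_no_shared_pair(self):
        spec = ModelSpec(2, n_continuous=2, n_binary=0, shared_pair=None)
        assert count_parameters(spec) == 1 + 8


class TestLogClassDensity:
    def test_single_binary_cell(self):
        spec = ModelSpec(1, n_continuous=1, n_binary=1, shared_pair=None)
        params = LcaParameters([1.0], [[0.5]], [[0.04]], 0.0, [[0.5]])
        row = np.array([np.nan, 1.0])
        mask = np.array([False, True])
        assert log_class_density(row, mask, params, 0, spec) == pytest.approx(
            np.log(0.5))

    def test_continuous_cell_at_class_mean(self):
        spec = ModelSpec(1, n_continuous=1, n_binary=0, shared_pair=None)
        params = LcaParameters([1.0], [[0.5]], [[0.04]], 0.0,
                               np.empty((1, 0)))
        val = log_class_density(np.array([0.5]), np.array([True]), params, 0,
                                spec)
        assert val == pytest.approx(np.log(1 / np.sqrt(2 * np.pi * 0.04)))

    def test_bivariate_pair_matches_scipy_mvn(self):
        spec = ModelSpec(1, n_continuous=2, n_binary=0, shared_pair=(0, 1))
        params = LcaParameters([1.0], [[0.4, 0.6]], [[0.04, 0.09]], -0.02,
                               np.empty((1, 0)))
        row = np.array([0.45, 0.5])
        ours = log_class_density(row, np.array([True, True]), params, 0, spec)
        cov = np.array([[0.04, -0.02], [-0.02, 0.09]])
        oracle = stats.multivariate_normal.logpdf(row, [0.4, 0.6], cov)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_pair_with_one_member_missing_uses_marginal(self):
        spec = ModelSpec(1, n_continuous=2, n_binary=0, shared_pair=(0, 1))
        params = LcaParameters([1.0], [[0.4, 0.6]], [[0.04, 0.09]], -0.02,
                               np.empty((1, 0)))
        row = np.array([0.45, np.nan])
        ours = log_class_density(row, np.array([True, False]), params, 0, spec)
        assert ours == pytest.approx(stats.norm.logpdf(0.45, 0.4, 0.2))

    def test_fully_missing_row_has_zero_log_density(self):
        spec = ModelSpec(1, n_continuous=2, n_binary=1, shared_pair=None)
        params = toy_params(k=1)
        row = np.full(3, np.nan)
        assert log_class_density(row, np.zeros(3, bool), params, 0, spec) == 0.0

    def test_vectorized_path_agrees_with_reference_loop(self, rng):
        spec = ModelSpec(3, n_continuous=8, n_binary=4, shared_pair=(5, 6))
        params = LcaParameters(
            mixing=[0.3, 0.3, 0.4],
            means=rng.uniform(0.2, 0.8, (3, 8)),
            variances=rng.uniform(0.01, 0.05, (3, 8)),
            shared_cov=0.005,
            probs=rng.uniform(0.1, 0.9, (3, 4)))
        values, _ = simulate_from_params(params, spec, 40, rng)
        values[rng.random((40, 12)) < 0.3] = np.nan
        mask = ~np.isnan(values)
        dense = lca._log_density_matrix(values, mask, params, spec)
        for i in range(0, 40, 7):
            for k in range(3):
                ref = log_class_density(values[i], mask[i], params, k, spec)
                assert dense[i, k] == pytest.approx(ref, abs=1e-10)


class TestESTep:
    def test_identical_classes_give_uniform_posteriors(self):
        spec = ModelSpec(2, n_continuous=2, n_binary=0, shared_pair=None)
        p = toy_params(k=1, nb=0)
        params = LcaParameters([0.5, 0.5], np.tile(p.means, (2, 1)),
                               np.tile(p.variances, (2, 1)), 0.0,
                               np.empty((2, 0)))
        values = np.array([[0.3, 0.4], [0.9, 0.1]])
        post, _ = e_step(values, params, spec)
        np.testing.assert_allclose(post, 0.5)

    def test_fully_missing_row_returns_prior(self):
        spec = ModelSpec(2, n_continuous=2, n_binary=1, shared_pair=None)
        params = toy_params()
        params.mixing = np.array([0.7, 0.3])
        post, _ = e_step(np.full((1, 3), np.nan), params, spec)
        np.testing.assert_allclose(post[0], [0.7, 0.3], atol=1e-12)

    def test_posterior_rows_sum_to_one(self, rng):
        spec = ModelSpec(4, n_continuous=8, n_binary=4)
        params = toy_params(k=4, nc=8, nb=4, shared_cov=0.003, seed=3)
        values, _ = simulate_from_params(params, spec, 60, rng)
        values[rng.random(values.shape) < 0.2] = np.nan
        post, ll = e_step(values, params, spec)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)
        assert np.isfinite(ll)

    def test_permutation_equivariance(self, rng):
        spec = ModelSpec(3, n_continuous=8, n_binary=4)
        params = toy_params(k=3, nc=8, nb=4, seed=5)
        values, _ = simulate_from_params(params, spec, 50, rng)
        perm = rng.permutation(50)
        post, _ = e_step(values, params, spec)
        post_p, _ = e_step(values[perm], params, spec)
        np.testing.assert_allclose(post_p, post[perm], atol=1e-12)


class TestMStep:
    def test_one_hot_posteriors_recover_subgroup_moments(self, rng):
        spec = ModelSpec(2, n_continuous=2, n_binary=1, shared_pair=None)
        values = np.column_stack([rng.uniform(0, 1, 30),
                                  rng.uniform(0, 1, 30),
                                  rng.integers(0, 2, 30).astype(float)])
        groups = np.repeat([0, 1], 15)
        r = np.eye(2)[groups]
        params = m_step(values, r, spec)
        for k in range(2):
            sub = values[groups == k]
            np.testing.assert_allclose(params.means[k], sub[:, :2].mean(0),
                                       atol=1e-12)
            np.testing.assert_allclose(params.variances[k], sub[:, :2].var(0),
                                       atol=1e-12)
            assert params.probs[k, 0] == pytest.approx(sub[:, 2].mean())

    def test_uniform_posteriors_give_identical_classes(self, rng):
        spec = ModelSpec(2, n_continuous=2, n_binary=0, shared_pair=None)
        values = rng.uniform(0, 1, (40, 2))
        params = m_step(values, np.full((40, 2), 0.5), spec)
        np.testing.assert_allclose(params.means[0], params.means[1])
        np.testing.assert_allclose(params.mixing, [0.5, 0.5])

    def test_weighted_moments_match_explicit_summation(self, rng):
        spec = ModelSpec(2, n_continuous=2, n_binary=1, shared_pair=(0, 1))
        values = np.column_stack([rng.uniform(0, 1, 25),
                                  rng.uniform(0, 1, 25),
                                  rng.integers(0, 2, 25).astype(float)])
        values[rng.random((25, 3)) < 0.2] = np.nan
        r = rng.dirichlet([1, 1], size=25)
        params = m_step(values, r, spec)
        mask = ~np.isnan(values)
        for k in range(2):
            for j in range(2):
                w = r[mask[:, j], k]
                x = values[mask[:, j], j]
                mu = (w * x).sum() / w.sum()
                assert params.means[k, j] == pytest.approx(mu, abs=1e-10)
                var = (w * (x - mu) ** 2).sum() / w.sum()
                assert params.variances[k, j] == pytest.approx(
                    var, abs=1e-10)
        both = mask[:, 0] & mask[:, 1]
        num = sum((r[both, k] * (values[both, 0] - params.means[k, 0])
                   * (values[both, 1] - params.means[k, 1])).sum()
                  for k in range(2))
        assert params.shared_cov == pytest.approx(num / r[both].sum(),
                                                  abs=1e-10)

    def test_variance_floor_applied(self):
        spec = ModelSpec(1, n_continuous=1, n_binary=0, shared_pair=None,
                         var_floor=1e-4)
        values = np.full((10, 1), 0.5)  # zero variance
        params = m_step(values, np.ones((10, 1)), spec)
        assert params.variances[0, 0] == spec.var_floor


class TestFit:
    def test_one_class_matches_sample_moments(self, rng):
        spec = ModelSpec(1, n_continuous=2, n_binary=1, shared_pair=(0, 1))
        truth = LcaParameters([1.0], [[0.4, 0.6]], [[0.02, 0.03]], 0.005,
                              [[0.3]])
        values, _ = simulate_from_params(truth, spec, 400, rng)
        res = fit(values, spec, seed=0)
        np.testing.assert_allclose(res.params.means[0], values[:, :2].mean(0),
                                   atol=1e-9)
        np.testing.assert_allclose(res.params.variances[0],
                                   values[:, :2].var(0), atol=1e-9)
        assert res.params.mixing[0] == 1.0

    def test_recovers_well_separated_classes(self, rng):
        spec = ModelSpec(2, n_continuous=2, n_binary=2, shared_pair=None)
        truth = LcaParameters(
            mixing=[0.6, 0.4], means=[[0.3, 0.3], [0.7, 0.7]],
            variances=[[0.016, 0.016], [0.016, 0.016]],  # 3+ SD separation
            shared_cov=0.0, probs=[[0.2, 0.2], [0.8, 0.8]])
        values, _ = simulate_from_params(truth, spec, 500, rng)
        res = fit(values, spec, n_starts=10, seed=1)
        order = np.argsort(res.params.means[:, 0])
        np.testing.assert_allclose(res.params.mixing[order], truth.mixing,
                                   atol=0.05)
        np.testing.assert_allclose(res.params.means[order], truth.means,
                                   atol=0.05)
        assert res.max_ll_decrease <= 1e-8

    def test_modal_is_argmax_and_canonical_order(self, rng):
        spec = ModelSpec(3, n_continuous=8, n_binary=4)
        params = toy_params(k=3, nc=8, nb=4, seed=2)
        values, _ = simulate_from_params(params, spec, 200, rng)
        res = fit(values, spec, n_starts=6, seed=0)
        np.testing.assert_array_equal(res.modal, res.posteriors.argmax(1))
        assert (np.diff(res.params.mixing) <= 1e-12).all()  # descending

    def test_matches_sklearn_gmm_on_pure_gaussian_data(self, rng):
        # independent library cross-check: diagonal-covariance mixture,
        # complete data, no shared pair, no binary indicators
        from sklearn.mixture import GaussianMixture
        spec = ModelSpec(2, n_continuous=3, n_binary=0, shared_pair=None,
                         var_floor=1e-6)
        truth = LcaParameters(
            mixing=[0.5, 0.5], means=[[0.3, 0.4, 0.3], [0.7, 0.6, 0.7]],
            variances=[[0.01] * 3, [0.01] * 3], shared_cov=0.0,
            probs=np.empty((2, 0)))
        values, _ = simulate_from_params(truth, spec, 300, rng)
        res = fit(values, spec, n_starts=10, seed=0, tol=1e-9)
        gmm = GaussianMixture(2, covariance_type="diag", reg_covar=1e-6,
                              n_init=10, random_state=0, tol=1e-9,
                              max_iter=2000).fit(values)
        assert res.log_likelihood == pytest.approx(
            gmm.score(values) * len(values), abs=0.05)

    def test_needs_at_least_k_rows(self):
        spec = ModelSpec(5, n_continuous=2, n_binary=0, shared_pair=None)
        with pytest.raises(ValueError, match="at least"):
            fit(np.zeros((3, 2)), spec)

    @HSET
    @given(st.integers(0, 10_000))
    def test_posteriors_valid_for_random_parameters(self, seed):
        rng = np.random.default_rng(seed)
        spec = ModelSpec(2, n_continuous=2, n_binary=1, shared_pair=None)
        params = toy_params(seed=seed)
        values, _ = simulate_from_params(params, spec, 20, rng)
        post, ll = e_step(values, params, spec)
        assert np.isfinite(ll)
        assert (post >= 0).all() and (post <= 1).all()
        np.testing.assert_allclose(post.sum(1), 1.0, atol=1e-9)


def test_parameters_roundtrip_through_dict():
    p = toy_params(k=3, nc=8, nb=4, shared_cov=-0.002, seed=9)
    q = LcaParameters.from_dict(p.to_dict())
    np.testing.assert_allclose(p.means, q.means)
    assert p.shared_cov == q.shared_cov
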