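import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mirtsel as m
from mirtsel.model_core import _log_prior_weights

from conftest import random_small_problem


class TestResponseProb:
    def test_zero_predictor_gives_half(self):
        assert m.response_prob(np.zeros(3), 0.0, np.array([1.7, -2.0, 0.3])) == 0.5

    def test_hand_value(self):
        # exp(3) / (1 + exp(3))
        p = m.response_prob(np.array([1.0, 1.0]), 1.0, np.array([1.0, 1.0]))
        assert p == pytest.approx(0.95257413, abs=1e-8)

    def test_saturation_no_overflow(self):
        p = m.response_prob(np.array([1.0]), 0.0, np.array([-40.0]))
        assert 0.0 < p < 1e-15
        assert np.isfinite(m.response_prob(np.array([200.0]), 100.0, np.array([3.0])))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            m.response_prob(np.array([np.nan]), 0.0, np.array([1.0]))

    @given(
        a=st.lists(st.floats(-3, 3), min_size=1, max_size=3),
        b=st.floats(-3, 3),
        t=st.floats(-4, 4),
    )
    @settings(deadline=None)
    def test_complement_symmetry(self, a, b, t):
        a = np.array(a)
        theta = np.full(a.size, t)
        p = m.response_prob(a, b, theta)
        q = m.response_prob(-a, -b, theta)
        assert p + q == pytest.approx(1.0, abs=1e-12)


class TestObservedLoglik:
    def test_constant_item_grid_free(self):
        params = m.ItemParams(np.zeros((1, 1)), np.zeros(1))
        sig = m.LatentCov(np.eye(1))
        Y = m.ResponseMatrix(np.array([[1], [0]]))
        for per_dim in (3, 7, 11):
            grid = m.build_grid(per_dim, (-4, 4), 1)
            ll = m.observed_loglik(params, sig, Y, grid)
            assert ll == pytest.approx(2 * np.log(0.5), abs=1e-12)

    def test_iid_subjects_add(self):
        params = m.ItemParams(np.array([[0.8]]), np.array([-0.3]))
        sig = m.LatentCov(np.eye(1))
        grid = m.build_grid(7, (-4, 4), 1)
        one = m.observed_loglik(params, sig, m.ResponseMatrix(np.array([[1], [0]])), grid)
        two = m.observed_loglik(
            params, sig, m.ResponseMatrix(np.array([[1], [0], [1], [0]])), grid
        )
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_matches_bruteforce_grid_sum(self):
        # independent straight-line oracle: explicit loops over subjects,
        # grid points and items
        rng = np.random.default_rng(7)
        params, sig, Y, grid = random_small_problem(rng, N=6, J=2, K=1, per_dim=3)
        phi = np.exp(_log_prior_weights(sig, grid.points))
        expected = 0.0
        for i in range(Y.N):
            tot = 0.0
            for g in range(grid.G):
                lik = 1.0
                for j in range(Y.J):
                    p = 1.0 / (1.0 + np.exp(-(grid.points[g] @ params.A[j] + params.b[j])))
                    lik *= p if Y.Y[i, j] == 1 else 1.0 - p
                tot += phi[g] * lik
            expected += np.log(tot)
        got = m.observed_loglik(params, sig, Y, grid)
        assert got == pytest.approx(expected, abs=1e-10)
        assert got <= 0.0

    def test_empty_grid_rejected(self):
        params = m.ItemParams(np.zeros((1, 1)), np.zeros(1))
        grid = m.GridSet(points=np.empty((0, 1)), per_dim=0, interval=(-1, 1))
        with pytest.raises(ValueError):
            m.observed_loglik(params, m.LatentCov(np.eye(1)), m.ResponseMatrix(np.array([[1]])), grid)

    def test_moving_b_toward_empirical_logit_improves(self):
        # one item, 3 of 4 correct: raising a wrong-signed b increases loglik
        Y = m.ResponseMatrix(np.array([[1], [1], [1], [0]]))
        sig = m.LatentCov(np.eye(1))
        grid = m.build_grid(11, (-4, 4), 1)
        lls = [
            m.observed_loglik(m.ItemParams(np.zeros((1, 1)), np.array([b])), sig, Y, grid)
            for b in (-1.0, 0.0, 0.5, np.log(3.0))
        ]
        assert all(x < y for x, y in zip(lls, lls[1:]))


class TestPenalizedObjective:
    def test_zero_eta_equals_loglik(self, small_instance, grid11_k2):
        cfg, model, Y = small_instance
        params, sig = model.item_params(), model.latent_cov()
        assert m.penalized_objective(params, sig, Y, grid11_k2, 0.0) == pytest.approx(
            m.observed_loglik(params, sig, Y, grid11_k2)
        )

    def test_linear_in_eta(self, small_instance, grid11_k2):
        cfg, model, Y = small_instance
        params, sig = model.item_params(), model.latent_cov()
        l1 = np.abs(params.A).sum()
        f1 = m.penalized_objective(params, sig, Y, grid11_k2, 1.0)
        f2 = m.penalized_objective(params, sig, Y, grid11_k2, 2.0)
        assert f1 - f2 == pytest.approx(l1, rel=1e-12)

    def test_negative_eta_rejected(self, small_instance, grid11_k2):
        cfg, model, Y = small_instance
        with pytest.raises(ValueError):
            m.penalized_objective(model.item_params(), model.latent_cov(), Y, grid11_k2, -0.1)

    def test_concave_in_b(self):
        # midpoint inequality on random b-triples at fixed A, Sigma, data
        rng = np.random.default_rng(3)
        params, sig, Y, grid = random_small_problem(rng, N=20, J=3, K=1, per_dim=5)
        for _ in range(10):
            b1 = rng.normal(0, 2, size=3)
            b2 = rng.normal(0, 2, size=3)
            f = lambda b: m.penalized_objective(
                m.ItemParams(params.A, b), sig, Y, grid, 0.5
            )
            mid = f((b1 + b2) / 2)
            assert mid >= 0.5 * (f(b1) + f(b2)) - 1e-10


class TestLoadingStructure:
    def test_threshold_semantics(self):
        params = m.ItemParams(np.array([[0.4], [0.6]]), np.zeros(2))
        assert m.loading_structure(params, tol=0.5).Lambda.tolist() == [[0], [1]]
        assert m.loading_structure(params).Lambda.tolist() == [[1], [1]]
        zero = m.ItemParams(np.zeros((2, 2)), np.zeros(2))
        assert not m.loading_structure(zero).Lambda.any()


class TestDomainTypes:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            m.ModelConfig(N=10, J=2, K=3)
        with pytest.raises(ValueError):
            m.ModelConfig(N=10, J=5, K=2, anchor_map={7: 0})
        cfg = m.ModelConfig(N=10, J=5, K=2, anchor_map={0: 0, 1: 1})
        mask = cfg.free_mask
        assert mask[0].tolist() == [True, False] and mask[1].tolist() == [False, True]
        assert mask[2:].all()

    def test_latent_cov_validation(self):
        with pytest.raises(ValueError):
            m.LatentCov(np.array([[1.0, 0.2], [0.3, 1.0]]))  # asymmetric
        with pytest.raises(ValueError):
            m.LatentCov(np.array([[2.0, 0.0], [0.0, 1.0]]))  # diagonal not 1
        with pytest.raises(ValueError):
            m.LatentCov(np.array([[1.0, 1.0], [1.0, 1.0]]))  # singular

    def test_response_matrix_validation(self):
        with pytest.raises(ValueError):
            m.ResponseMatrix(np.array([[0, 2]]))
        with pytest.warns(UserWarning):
            m.ResponseMatrix(np.array([[1, 0], [1, 1]]))  # constant column
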