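import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mirtsel as m
from mirtsel.mstep import ItemSubproblem, kkt_violation


class TestSoftThreshold:
    @pytest.mark.parametrize("x,lam,out", [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), (-3.0, 1.0, -2.0)])
    def test_values(self, x, lam, out):
        assert m.soft_threshold(x, lam) == out

    @given(st.floats(-100, 100))
    @settings(deadline=None)
    def test_zero_lambda_is_identity(self, x):
        assert m.soft_threshold(x, 0.0) == x

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            m.soft_threshold(1.0, -0.1)


def _toy_subproblem(eta, w1, w0, theta=None):
    theta = np.array([[-1.0], [1.0]]) if theta is None else theta
    return ItemSubproblem(
        theta=theta,
        w=np.vstack([w0, w1]),
        eta=eta,
        fixed_zero_mask=np.zeros(theta.shape[1], dtype=bool),
    )


class TestFitItemWeightedL1:
    def test_full_shrinkage_closed_form_intercept(self):
        # eta large enough to kill every loading: b = log(W1 / W0)
        sub = _toy_subproblem(eta=1e4, w1=np.array([10.0, 20.0]), w0=np.array([30.0, 40.0]))
        a, b, obj = m.fit_item_weighted_l1(sub)
        assert a[0] == 0.0
        assert b == pytest.approx(np.log(30.0 / 70.0), abs=1e-10)
        assert b == pytest.approx(-0.84729786, abs=1e-8)

    def test_matches_dense_grid_search_oracle(self):
        # eta=0, K=1, 2-point grid: independent coarse-to-fine 2-D grid search
        w1 = np.array([12.0, 3.0])
        w0 = np.array([4.0, 9.0])
        theta = np.array([[-1.0], [1.0]])
        sub = _toy_subproblem(eta=0.0, w1=w1, w0=w0, theta=theta)
        a_hat, b_hat, _ = m.fit_item_weighted_l1(sub)

        def obj(a, b):
            x = theta[:, 0] * a + b
            p = 1.0 / (1.0 + np.exp(-x))
            return float(w1 @ np.log(p) + w0 @ np.log(1.0 - p))

        lo_a, hi_a, lo_b, hi_b = -5.0, 5.0, -5.0, 5.0
        best = None
        for _ in range(8):  # successive refinement of a dense grid
            aa = np.linspace(lo_a, hi_a, 41)
            bb = np.linspace(lo_b, hi_b, 41)
            vals = [(obj(a, b), a, b) for a in aa for b in bb]
            best = max(vals)
            _, a0, b0 = best
            da, db = (hi_a - lo_a) / 40, (hi_b - lo_b) / 40
            lo_a, hi_a, lo_b, hi_b = a0 - da, a0 + da, b0 - db, b0 + db
        assert a_hat[0] == pytest.approx(best[1], abs=1e-4)
        assert b_hat == pytest.approx(best[2], abs=1e-4)

    def test_mask_forces_exact_zero(self):
        sub = ItemSubproblem(
            theta=np.array([[-1.0], [1.0]]),
            w=np.array([[30.0, 40.0], [10.0, 20.0]]),
            eta=0.0,
            fixed_zero_mask=np.ones(1, dtype=bool),
        )
        a, b, _ = m.fit_item_weighted_l1(sub)
        assert a[0] == 0.0
        assert b == pytest.approx(np.log(30.0 / 70.0), abs=1e-10)

    def test_inactive_coordinates_are_exact_zeros(self):
        rng = np.random.default_rng(41)
        grid = m.build_grid(5, (-2.4, 2.4), 2)
        w1 = rng.uniform(0, 1, grid.G)
        w0 = rng.uniform(0, 1, grid.G)
        sub = ItemSubproblem(
            theta=grid.points,
            w=np.vstack([w0, w1]),
            eta=5.0,
            fixed_zero_mask=np.zeros(2, dtype=bool),
        )
        a, b, _ = m.fit_item_weighted_l1(sub)
        assert all(x == 0.0 for x in a)  # exact zeros, not small values

    def test_separation_clips_intercept(self):
        sub = _toy_subproblem(eta=0.0, w1=np.array([5.0, 5.0]), w0=np.zeros(2))
        with pytest.warns(UserWarning):
            a, b, _ = m.fit_item_weighted_l1(sub)
        assert b == 30.0

    def test_kkt_conditions_at_solution(self):
        rng = np.random.default_rng(43)
        grid = m.build_grid(5, (-2.4, 2.4), 2)
        for eta in (0.0, 0.5, 3.0):
            w1 = rng.uniform(0, 2, grid.G)
            w0 = rng.uniform(0, 2, grid.G)
            sub = ItemSubproblem(
                theta=grid.points,
                w=np.vstack([w0, w1]),
                eta=eta,
                fixed_zero_mask=np.zeros(2, dtype=bool),
            )
            a, b, _ = m.fit_item_weighted_l1(sub)
            X = np.vstack([grid.points, grid.points])
            z = np.concatenate([np.ones(grid.G), np.zeros(grid.G)])
            w = np.concatenate([w1, w0])
            assert kkt_violation(X, z, w, a, b, eta, np.ones(2, bool)) < 1e-6

    def test_warm_start_path_continuity(self):
        # refits along a fine eta path move continuously
        rng = np.random.default_rng(47)
        grid = m.build_grid(5, (-2.4, 2.4), 1)
        w1 = rng.uniform(0, 3, grid.G)
        w0 = rng.uniform(0, 3, grid.G)
        a_prev, b_prev = None, None
        for eta in np.linspace(3.0, 0.0, 16):
            sub = ItemSubproblem(
                theta=grid.points,
                w=np.vstack([w0, w1]),
                eta=float(eta),
                fixed_zero_mask=np.zeros(1, dtype=bool),
                a_init=a_prev,
                b_init=b_prev if b_prev is not None else 0.0,
            )
            a, b, _ = m.fit_item_weighted_l1(sub)
            if a_prev is not None:
                assert abs(a[0] - a_prev[0]) < 0.5
            a_prev, b_prev = a, b


class TestUpdateCovariance:
    def test_identity_fixed_point(self):
        out = m.update_covariance(np.eye(2), m.LatentCov(np.eye(2)), N=100)
        np.testing.assert_allclose(out.Sigma, np.eye(2), atol=1e-8)

    @pytest.mark.parametrize("s", [0.3, -0.45, 0.05])
    def test_unit_diag_scatter_stationary_at_offdiag(self, s):
        # for unit-diagonal S*, the constrained optimum has rho = s
        S = np.array([[1.0, s], [s, 1.0]])
        out = m.update_covariance(S, m.LatentCov(np.eye(2)), N=50)
        assert out.Sigma[0, 1] == pytest.approx(s, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        # independent 1-D search over rho for a non-unit-diagonal S*
        S = np.array([[0.9, 0.25], [0.25, 1.2]])
        out = m.update_covariance(S, m.LatentCov(np.eye(2)), N=10)

        def q0(rho):
            Sig = np.array([[1.0, rho], [rho, 1.0]])
            return m.q0_value(m.LatentCov(Sig), S, N=10)

        rhos = np.linspace(-0.999, 0.999, 20001)
        best = rhos[np.argmax([q0(r) for r in rhos])]
        assert out.Sigma[0, 1] == pytest.approx(best, abs=1e-4)
        assert q0(out.Sigma[0, 1]) >= q0(best) - 1e-8

    def test_monotone_ascent_and_constraints(self):
        rng = np.random.default_rng(53)
        for _ in range(5):
            M = rng.normal(size=(3, 3))
            S = M @ M.T / 3.0
            init = m.LatentCov(np.eye(3))
            out = m.update_covariance(S, init, N=20)
            np.testing.assert_allclose(np.diag(out.Sigma), 1.0, atol=1e-12)
            assert np.linalg.eigvalsh(out.Sigma).min() > 0
            assert m.q0_value(out, S, 20) >= m.q0_value(init, S, 20) - 1e-10
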