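"""M-step solvers: weighted L1-penalized logistic regression per item and
the unit-diagonal covariance update.

Each item subproblem maximizes a weighted L1-penalized logistic
log-likelihood over pseudo-observations (design row theta, response z,
non-negative weight w):

    max_{a, b}  sum_m w_m [ z_m log p_m + (1 - z_m) log(1 - p_m) ] - eta ||a||_1,

with p_m = expit(theta_m' a + b) and the intercept b unpenalized.  The
solver is iteratively reweighted least squares with coordinate-wise
soft-thresholding on the weighted quadratic surrogate (the coordinate
descent family used for lasso-penalized GLMs); curvature uses the exact
logistic variance w p (1 - p).  Coordinates are swept in fixed order
(loadings 1..K then the intercept), so runs are bitwise reproducible.
Penalized coordinates land on exact zeros.

The covariance update maximizes

    Q0(Sigma) = -N/2 { K log(2 pi) + log det Sigma + tr(Sigma^{-1} S*) }

over unit-diagonal positive-definite Sigma by projected gradient ascent
with backtracking (monotone in Q0); the feasibility map symmetrizes,
clips eigenvalues at 1e-6 and rescales to a unit diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, log_expit

from .model_core import LatentCov

__all__ = [
    "ItemSubproblem",
    "soft_threshold",
    "fit_item_weighted_l1",
    "fit_weighted_logistic",
    "kkt_violation",
    "update_covariance",
]

_B_CLIP = 30.0  # intercept bound under complete separation


def soft_threshold(x: float, lam: float) -> float:
    """sign(x) * max(|x| - lam, 0), the proximal map of lam * |.|."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


@dataclass
class ItemSubproblem:
    """One item's weighted L1 logistic subproblem on the 2 x G artificial data.

    ``theta`` is the (G, K) grid; ``w`` the (2, G) weights with row z the
    weight of pseudo-response z at each grid point; ``fixed_zero_mask``
    marks loadings pinned at zero (anchor constraints).
    """

    theta: np.ndarray
    w: np.ndarray
    eta: float
    fixed_zero_mask: np.ndarray
    a_init: np.ndarray | None = None
    b_init: float = 0.0


def _objective(X, z, w, a, b, eta):
    x = X @ a + b
    ll = float(w @ (z * log_expit(x) + (1.0 - z) * log_expit(-x)))
    return ll - eta * np.abs(a).sum()


def fit_weighted_logistic(
    X: np.ndarray,
    z: np.ndarray,
    w: np.ndarray,
    eta: float,
    free: np.ndarray,
    a_init: np.ndarray | None = None,
    b_init: float = 0.0,
    inner_tol: float = 1e-10,
    outer_tol: float = 1e-13,
    max_outer: int = 500,
    max_inner: int = 1000,
):
    """Maximize the weighted L1-penalized logistic log-likelihood.

    Generic over the pseudo-data: rows (X_m, z_m, w_m) may be the 2 x G
    artificial observations or the N x G naive augmented observations —
    the same solver serves both EM variants.  Returns
    ``(a, b, objective, warn_flags)`` with masked coordinates exactly zero.
    """
    if eta < 0:
        raise ValueError("eta must be non-negative")
    X = np.asarray(X, dtype=float)
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    K = X.shape[1]
    free = np.asarray(free, dtype=bool)
    warn_flags: list[str] = []

    a = np.zeros(K) if a_init is None else np.array(a_init, dtype=float)
    a[~free] = 0.0
    b = float(b_init)

    W1 = float(w[z == 1].sum())
    W0 = float(w[z == 0].sum())
    if W1 <= 0.0 or W0 <= 0.0:
        # complete separation in the pseudo-responses: the intercept diverges
        a = np.zeros(K)
        b = _B_CLIP if W0 <= 0.0 else -_B_CLIP
        warn_flags.append("separation")
        warnings.warn(
            "all pseudo-weight in one response class; intercept clipped",
            UserWarning,
            stacklevel=2,
        )
        return a, b, _objective(X, z, w, a, b, eta), warn_flags

    free_idx = np.flatnonzero(free)
    Xsq = X * X
    obj = _objective(X, z, w, a, b, eta)

    for _ in range(max_outer):
        x = X @ a + b
        p = expit(x)
        s = w * (z - p)  # score contributions
        v = w * np.clip(p * (1.0 - p), 1e-10, None)
        v[w == 0.0] = 0.0

        a_new = a.copy()
        b_new = b
        res = s.copy()  # v * (working response - current fit)
        denom_a = v @ Xsq
        denom_b = float(v.sum())
        for _ in range(max_inner):
            delta = 0.0
            for k in free_idx:
                if denom_a[k] <= 0.0:
                    continue
                rho = float(X[:, k] @ res) + denom_a[k] * a_new[k]
                cand = soft_threshold(rho, eta) / denom_a[k]
                if cand != a_new[k]:
                    res -= v * X[:, k] * (cand - a_new[k])
                    delta = max(delta, abs(cand - a_new[k]))
                    a_new[k] = cand
            if denom_b > 0.0:
                cand = float(res.sum()) / denom_b + b_new
                if cand != b_new:
                    res -= v * (cand - b_new)
                    delta = max(delta, abs(cand - b_new))
                    b_new = cand
            if delta < inner_tol:
                break

        # ascent safeguard: the quadratic surrogate can overshoot, so halve
        # the step toward the previous iterate until the true objective
        # does not decrease
        obj_new = _objective(X, z, w, a_new, b_new, eta)
        step = 1.0
        while obj_new < obj and step > 1e-12:
            step *= 0.5
            a_new = a + step * (a_new - a)
            b_new = b + step * (b_new - b)
            obj_new = _objective(X, z, w, a_new, b_new, eta)
        moved = max(np.max(np.abs(a_new - a)), abs(b_new - b))
        a, b = a_new, b_new
        if abs(obj_new - obj) < outer_tol and moved < 1e-9:
            obj = obj_new
            break
        obj = obj_new
    return a, b, obj, warn_flags


def fit_items_weighted_l1_multi(
    theta: np.ndarray,
    w1: np.ndarray,
    w0: np.ndarray,
    eta: float,
    free: np.ndarray,
    A_init: np.ndarray,
    b_init: np.ndarray,
    inner_tol: float = 1e-10,
    outer_tol: float = 1e-13,
    max_outer: int = 500,
    max_inner: int = 1000,
):
    """Solve all J item subproblems on the shared grid simultaneously.

    Identical mathematics to :func:`fit_weighted_logistic` applied to each
    item's 2 x G artificial data — the same coordinate order, curvature and
    ascent safeguard — but with the J independent problems advanced in
    lock-step as (J, G) array operations, which is much faster than a
    Python loop over items.  ``w1``/``w0`` are (J, G) weights for the
    z = 1 / z = 0 pseudo-responses.  Returns ``(A, b, warn_flags)``.
    """
    J, G = w1.shape
    K = theta.shape[1]
    A = np.array(A_init, dtype=float)
    A[~free] = 0.0
    b = np.array(b_init, dtype=float)
    warn_flags: list[str] = []

    f = w1 + w0  # (J, G)
    W1 = w1.sum(axis=1)
    W0 = w0.sum(axis=1)
    degenerate = (W1 <= 0.0) | (W0 <= 0.0)
    for j in np.flatnonzero(degenerate):
        A[j] = 0.0
        b[j] = _B_CLIP if W0[j] <= 0.0 else -_B_CLIP
        warn_flags.append(f"separation on item {j}; intercept clipped")
    active = ~degenerate

    theta_sq = theta * theta  # (G, K)

    def objective(A_, b_):
        x = A_ @ theta.T + b_[:, None]
        val = (w1 * log_expit(x)).sum(axis=1) + (w0 * log_expit(-x)).sum(axis=1)
        return val - eta * np.abs(A_).sum(axis=1)

    obj = objective(A, b)
    for _ in range(max_outer):
        if not active.any():
            break
        x = A @ theta.T + b[:, None]
        p = expit(x)
        s = w1 - f * p
        v = f * np.clip(p * (1.0 - p), 1e-10, None)
        v[f == 0.0] = 0.0

        A_new = A.copy()
        b_new = b.copy()
        res = s.copy()
        denom_a = v @ theta_sq  # (J, K)
        denom_b = v.sum(axis=1)  # (J,)
        for _ in range(max_inner):
            delta = np.zeros(J)
            for k in range(K):
                ok = active & free[:, k] & (denom_a[:, k] > 0.0)
                if not ok.any():
                    continue
                rho = res @ theta[:, k] + denom_a[:, k] * A_new[:, k]
                cand = np.where(ok, soft_threshold(rho, eta) / np.where(denom_a[:, k] > 0, denom_a[:, k], 1.0), A_new[:, k])
                step_k = cand - A_new[:, k]
                moved = ok & (step_k != 0.0)
                if moved.any():
                    res[moved] -= v[moved] * theta[:, k] * step_k[moved, None]
                    delta = np.maximum(delta, np.where(moved, np.abs(step_k), 0.0))
                    A_new[:, k] = np.where(moved, cand, A_new[:, k])
            okb = active & (denom_b > 0.0)
            cand_b = np.where(okb, res.sum(axis=1) / np.where(denom_b > 0, denom_b, 1.0) + b_new, b_new)
            step_b = cand_b - b_new
            movedb = okb & (step_b != 0.0)
            if movedb.any():
                res[movedb] -= v[movedb] * step_b[movedb, None]
                delta = np.maximum(delta, np.where(movedb, np.abs(step_b), 0.0))
                b_new = np.where(movedb, cand_b, b_new)
            if delta.max() < inner_tol:
                break

        obj_new = objective(A_new, b_new)
        # per-item ascent safeguard (step-halving toward the old iterate);
        # the comparison is noise-guarded: per-item objectives are O(N), so
        # decreases below float resolution must not trigger halving
        noise = 1e-12 * (1.0 + np.abs(obj))
        bad = active & (obj_new < obj - noise)
        halvings = 0
        while bad.any() and halvings < 50:
            A_new[bad] = A[bad] + 0.5 * (A_new[bad] - A[bad])
            b_new[bad] = b[bad] + 0.5 * (b_new[bad] - b[bad])
            obj_new = objective(A_new, b_new)
            bad = active & (obj_new < obj - noise)
            halvings += 1
        # an item is finished once its IRLS step no longer moves it; the
        # movement threshold tracks the coordinate tolerance
        moved = np.maximum(np.abs(A_new - A).max(axis=1), np.abs(b_new - b))
        done = active & (moved < max(10.0 * inner_tol, 1e-15))
        A, b, obj = A_new, b_new, obj_new
        active = active & ~done
    return A, b, warn_flags


def fit_item_weighted_l1(sub: ItemSubproblem):
    """Solve one item's M-step on its 2 x G artificial data.

    Returns ``(a_j, b_j, objective)`` where the objective is the achieved
    penalized item surrogate.
    """
    G = sub.theta.shape[0]
    X = np.vstack([sub.theta, sub.theta])
    z = np.concatenate([np.ones(G), np.zeros(G)])
    w = np.concatenate([sub.w[1], sub.w[0]])
    a, b, obj, _ = fit_weighted_logistic(
        X,
        z,
        w,
        sub.eta,
        free=~np.asarray(sub.fixed_zero_mask, dtype=bool),
        a_init=sub.a_init,
        b_init=sub.b_init,
    )
    return a, b, obj


def kkt_violation(X, z, w, a, b, eta, free) -> float:
    """Maximum violation of the subgradient stationarity conditions.

    For free coordinates: |score_k - eta sign(a_k)| at active coordinates
    and max(0, |score_k| - eta) at zeros; for the intercept: |score|.
    """
    X = np.asarray(X, dtype=float)
    p = expit(X @ a + b)
    s = np.asarray(w) * (np.asarray(z, dtype=float) - p)
    score = X.T @ s
    viol = abs(float(s.sum()))
    for k in np.flatnonzero(np.asarray(free, dtype=bool)):
        if a[k] != 0.0:
            viol = max(viol, abs(score[k] - eta * np.sign(a[k])))
        else:
            viol = max(viol, max(0.0, abs(score[k]) - eta))
    return viol


def _neg_q0_core(Sigma: np.ndarray, S_star: np.ndarray) -> float:
    """log det Sigma + tr(Sigma^{-1} S*), the N-free part to minimize."""
    c, low = cho_factor(Sigma)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    return logdet + float(np.trace(cho_solve((c, low), S_star)))


def _project_correlation(M: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Map a symmetric matrix to a unit-diagonal positive-definite one:
    eigenvalue clip at ``eig_floor`` then D^{-1/2} M D^{-1/2} rescaling."""
    M = 0.5 * (M + M.T)
    for _ in range(50):
        vals, vecs = np.linalg.eigh(M)
        if vals.min() < eig_floor:
            vals = np.clip(vals, eig_floor, None)
            M = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(M))
        M = M / np.outer(d, d)
        np.fill_diagonal(M, 1.0)
        M = 0.5 * (M + M.T)
        if np.linalg.eigvalsh(M).min() >= eig_floor * 0.5:
            return M
    return M


def update_covariance(
    S_star: np.ndarray,
    sigma_init: LatentCov,
    N: int,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> LatentCov:
    """Maximize Q0 over unit-diagonal positive-definite Sigma.

    Projected gradient ascent with backtracking on Q0 (monotone by
    construction); the projected gradient is the Q0 gradient with the
    diagonal zeroed (the tangent space of the diag(Sigma) = 1 constraint).
    Stops when its max-norm, on the N-free scale, falls below ``tol``.
    """
    K = sigma_init.K
    if K == 1:
        return LatentCov(np.array([[1.0]]))
    Sigma = sigma_init.Sigma.copy()
    g = _neg_q0_core(Sigma, S_star)
    step = 1.0
    for _ in range(max_iter):
        inv = np.linalg.inv(Sigma)
        grad = inv - inv @ S_star @ inv  # gradient of the part to minimize, x2
        grad = 0.5 * (grad + grad.T)
        np.fill_diagonal(grad, 0.0)
        gnorm = np.abs(grad).max()
        if gnorm < tol:
            return LatentCov(Sigma)
        accepted = False
        t = step
        for _ in range(60):
            cand = _project_correlation(Sigma - t * grad)
            g_cand = _neg_q0_core(cand, S_star)
            if g_cand < g - 1e-4 * t * gnorm**2:
                Sigma, g = cand, g_cand
                step = min(t * 2.0, 1e3)
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
    inv = np.linalg.inv(Sigma)
    grad = inv - inv @ S_star @ inv
    np.fill_diagonal(grad, 0.0)
    if np.abs(grad).max() >= tol:
        warnings.warn(
            "covariance update stopped before reaching stationarity",
            UserWarning,
            stacklevel=2,
        )
    return LatentCov(Sigma)
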