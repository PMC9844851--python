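"""Core domain types and likelihood functions for the M2PL model.

The multidimensional two-parameter logistic (M2PL) model links a binary
response of subject i to item j to a K-dimensional latent trait vector
theta_i through

    P(y_ij = 1 | theta_i) = expit(a_j' theta_i + b_j),

where a_j (discriminations, a row of the J x K loading matrix A) and b_j
(difficulty/intercept) are the item parameters and theta_i ~ N(0, Sigma)
with a unit-diagonal covariance Sigma.  Latent variable selection asks
which entries of A are non-zero; the support pattern is the binary
loading structure Lambda with lambda_jk = I(a_jk != 0).

Identification: a small set of *anchor items* is constrained to load on
exactly one pre-specified trait each (all their other loadings fixed at
zero), which resolves rotational indeterminacy; unit variances on the
traits fix the latent scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import multivariate_normal

__all__ = [
    "ModelConfig",
    "ItemParams",
    "LatentCov",
    "ResponseMatrix",
    "LoadingStructure",
    "response_prob",
    "observed_loglik",
    "penalized_objective",
    "loading_structure",
]


@dataclass(frozen=True)
class ModelConfig:
    """Dimensions and identification constraints of an M2PL model.

    Parameters
    ----------
    N, J, K
        Number of subjects, items and latent traits.
    anchor_map
        Mapping ``item index -> trait index`` (0-based).  Each listed item
        loads on exactly that one trait; all its other loadings are fixed
        at zero throughout estimation.
    """

    N: int
    J: int
    K: int
    anchor_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.K > self.J:
            raise ValueError(f"K={self.K} must not exceed J={self.J}")
        if self.N <= 0 or self.J <= 0 or self.K <= 0:
            raise ValueError("N, J, K must be positive")
        for j, k in self.anchor_map.items():
            if not (0 <= j < self.J):
                raise ValueError(f"anchor item {j} outside 0..{self.J - 1}")
            if not (0 <= k < self.K):
                raise ValueError(f"anchor trait {k} outside 0..{self.K - 1}")

    @property
    def free_mask(self) -> np.ndarray:
        """J x K boolean mask; False where a loading is pinned at zero."""
        mask = np.ones((self.J, self.K), dtype=bool)
        for j, k in self.anchor_map.items():
            mask[j, :] = False
            mask[j, k] = True
        return mask


@dataclass
class ItemParams:
    """Item parameters: discriminations ``A`` (J x K) and difficulties ``b`` (J,)."""

    A: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.A.ndim != 2 or self.b.ndim != 1 or self.A.shape[0] != self.b.shape[0]:
            raise ValueError("A must be J x K and b length J")
        if not (np.isfinite(self.A).all() and np.isfinite(self.b).all()):
            raise ValueError("item parameters must be finite")

    @property
    def J(self) -> int:
        return self.A.shape[0]

    @property
    def K(self) -> int:
        return self.A.shape[1]

    def copy(self) -> "ItemParams":
        return ItemParams(self.A.copy(), self.b.copy())

    def check_anchors(self, config: ModelConfig, atol: float = 0.0) -> None:
        """Verify that anchor-fixed zero positions are exactly zero."""
        bad = np.abs(self.A[~config.free_mask])
        if bad.size and bad.max() > atol:
            raise ValueError("anchor-fixed loadings are not zero")


@dataclass
class LatentCov:
    """Unit-diagonal positive-definite covariance of the latent traits."""

    Sigma: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.Sigma, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("Sigma must be square")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("Sigma must be symmetric")
        if not np.allclose(np.diag(S), 1.0, atol=1e-8):
            raise ValueError("Sigma must have unit diagonal")
        if np.linalg.eigvalsh(S).min() <= 1e-8:
            raise ValueError("Sigma must be positive definite")
        self.Sigma = 0.5 * (S + S.T)

    @property
    def K(self) -> int:
        return self.Sigma.shape[0]


@dataclass
class ResponseMatrix:
    """Binary N x J response matrix (0 = incorrect/no, 1 = correct/yes)."""

    Y: np.ndarray

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y)
        if Y.ndim != 2:
            raise ValueError("Y must be two-dimensional")
        if not np.isin(Y, (0, 1)).all():
            raise ValueError("responses must be coded 0/1 with no missing values")
        self.Y = Y.astype(np.int8)
        col_means = self.Y.mean(axis=0)
        degenerate = np.flatnonzero((col_means == 0.0) | (col_means == 1.0))
        if degenerate.size:
            warnings.warn(
                f"items {degenerate.tolist()} have constant responses; "
                "their parameters are not identified",
                UserWarning,
                stacklevel=2,
            )

    @property
    def N(self) -> int:
        return self.Y.shape[0]

    @property
    def J(self) -> int:
        return self.Y.shape[1]


@dataclass
class LoadingStructure:
    """Binary support pattern of the loading matrix, lambda_jk = I(a_jk != 0)."""

    Lambda: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.Lambda)
        if not np.isin(L, (0, 1)).all():
            raise ValueError("Lambda entries must be 0/1")
        self.Lambda = L.astype(np.int8)


def response_prob(a_j: np.ndarray, b_j: float, theta: np.ndarray) -> float | np.ndarray:
    """M2PL response probability expit(a_j' theta + b_j).

    ``theta`` may be a single K-vector or an array of row vectors; the
    computation is overflow-safe for arbitrarily large linear predictors.
    """
    a_j = np.asarray(a_j, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (np.isfinite(a_j).all() and np.isfinite(theta).all() and np.isfinite(b_j)):
        raise ValueError("response_prob requires finite inputs")
    x = theta @ a_j + b_j
    return expit(x)


def _log_item_probs(params: ItemParams, points: np.ndarray):
    """Return (log F, log(1-F)) at every grid point, shapes (G, J)."""
    x = points @ params.A.T + params.b  # (G, J)
    return log_expit(x), log_expit(-x)


def _log_prior_weights(sigma: LatentCov, points: np.ndarray) -> np.ndarray:
    """Log prior mass of each grid point, normalized over the grid."""
    logphi = multivariate_normal.logpdf(points, mean=np.zeros(sigma.K), cov=sigma.Sigma)
    logphi = np.atleast_1d(logphi)
    return logphi - logsumexp(logphi)


def _pattern_loglik(Y: np.ndarray, logF: np.ndarray, log1mF: np.ndarray) -> np.ndarray:
    """Per-row conditional log-likelihood at each grid point, shape (rows, G)."""
    Yf = Y.astype(float)
    return Yf @ logF.T + (1.0 - Yf) @ log1mF.T


def observed_loglik(params: ItemParams, sigma: LatentCov, Y: ResponseMatrix, grid) -> float:
    """Marginal log-likelihood of the observed responses on a quadrature grid.

    The integral over theta is replaced by a sum over the fixed grid with
    the normal prior discretized (normalized) on the grid, so a model with
    a constant response probability yields exactly N * log(p) regardless
    of the grid.
    """
    if grid.G == 0:
        raise ValueError("quadrature grid must be non-empty")
    logw = _log_prior_weights(sigma, grid.points)
    logF, log1mF = _log_item_probs(params, grid.points)
    ll = _pattern_loglik(Y.Y, logF, log1mF)  # (N, G)
    return float(logsumexp(ll + logw, axis=1).sum())


def penalized_objective(
    params: ItemParams,
    sigma: LatentCov,
    Y: ResponseMatrix,
    grid,
    eta: float,
) -> float:
    """L1-penalized marginal log-likelihood  l(A,b,Sigma|Y) - eta * ||A||_1."""
    if eta < 0:
        raise ValueError("eta must be non-negative")
    return observed_loglik(params, sigma, Y, grid) - eta * np.abs(params.A).sum()


def loading_structure(params: ItemParams, tol: float = 0.0) -> LoadingStructure:
    """Binary support of the loading matrix; entries with |a_jk| <= tol count as zero."""
    return LoadingStructure((np.abs(params.A) > tol).astype(np.int8))
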