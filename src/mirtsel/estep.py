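"""E-step quantities: artificial data, scatter matrix, and Q-function pieces.

The conditional expectation of the complete-data log-likelihood splits into
a covariance part Q0 and one item part Qj per item.  Each Qj can be written
two equivalent ways:

* the *naive* form: a weighted logistic log-likelihood over the N x G
  augmented observations (y_ij, theta^(g)) with weights p(theta^(g)|y_i);
* the *weighted* form: the same sum regrouped over 2 x G artificial
  observations (z, theta^(g)), z in {0,1}, with weights
  w_j(z, theta^(g)) = sum_i I(y_ij = z) p(theta^(g)|y_i).

The regrouping is an exact algebraic identity; the weighted form is what
makes the accelerated M-step O(2G) instead of O(NG).  The classical
Bock–Aitkin artificial data appear as f_g = sum_i p(theta^(g)|y_i)
("expected sample size" at ability level g) and r_jg = sum_i y_ij
p(theta^(g)|y_i) ("expected frequency" of a correct response), with
w_j(1,g) = r_jg and w_j(0,g) = f_g - r_jg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import log_expit

from .model_core import ItemParams, LatentCov, ResponseMatrix
from .quadrature import GridSet, PosteriorTable

__all__ = [
    "ArtificialData",
    "QComponents",
    "artificial_weights",
    "scatter_matrix",
    "q0_value",
    "qj_value",
    "qj_weighted",
    "qj_naive",
    "q_components",
]

# weights this small cannot move any estimate at the tolerances we work to,
# and subnormals slow the M-step down
_WEIGHT_FLOOR = 1e-300


@dataclass
class ArtificialData:
    """Per-item weights on the 2 x G artificial observations.

    ``w`` has shape (J, 2, G) with ``w[j, z, g]`` the weight of the pseudo
    observation (z, theta^(g)) for item j; ``f`` (G,) is the expected
    sample size per ability level and ``r`` (J, G) the expected
    correct-response frequency, so ``w[j,1] == r[j]`` and
    ``w[j,0] == f - r[j]``.
    """

    w: np.ndarray
    f: np.ndarray
    r: np.ndarray

    @property
    def G(self) -> int:
        return self.f.shape[0]

    @property
    def J(self) -> int:
        return self.r.shape[0]


@dataclass
class QComponents:
    """The surrogate Q decomposed as q0 + sum_j qj."""

    q0: float
    qj: np.ndarray

    @property
    def total(self) -> float:
        return float(self.q0 + self.qj.sum())


def artificial_weights(Y: ResponseMatrix, post: PosteriorTable) -> ArtificialData:
    """Collapse the posterior table into the 2 x G artificial data per item."""
    if post.patterns.shape[1] != Y.J or post.N != Y.N:
        raise ValueError("posterior table does not match the response matrix")
    counted = post.pattern_counts[:, None] * post.weights  # (P, G)
    f = counted.sum(axis=0)  # (G,)
    r = post.patterns.T.astype(float) @ counted  # (J, G)
    w = np.stack([f[None, :] - r, r], axis=1)  # (J, 2, G)
    np.clip(w, 0.0, None, out=w)
    w[w < _WEIGHT_FLOOR] = 0.0
    return ArtificialData(w=w, f=f, r=r)


def scatter_matrix(post: PosteriorTable, grid: GridSet) -> np.ndarray:
    """Posterior second-moment matrix S* = N^{-1} sum_i sum_g theta theta' p(theta|y_i)."""
    f = post.pattern_counts @ post.weights  # (G,)
    S = grid.points.T @ (f[:, None] * grid.points) / post.N
    return 0.5 * (S + S.T)


def q0_value(sigma: LatentCov, S_star: np.ndarray, N: int) -> float:
    """Expected Gaussian log-density part of the surrogate,

        Q0 = -1/2 { N K log(2 pi) + N log det Sigma + N tr(Sigma^{-1} S*) }.

    The log-determinant comes from a Cholesky factorization.
    """
    K = sigma.K
    try:
        c, low = cho_factor(sigma.Sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by LatentCov
        raise ValueError("Sigma must be positive definite") from exc
    logdet = 2.0 * np.log(np.diag(c)).sum()
    trace = float(np.trace(cho_solve((c, low), S_star)))
    return -0.5 * N * (K * np.log(2 * np.pi) + logdet + trace)


def _item_logprobs(a_j: np.ndarray, b_j: float, points: np.ndarray):
    x = points @ np.asarray(a_j, dtype=float) + b_j
    return log_expit(x), log_expit(-x)


def qj_weighted(
    a_j: np.ndarray,
    b_j: float,
    w_j: np.ndarray,
    grid: GridSet,
    eta: float = 0.0,
) -> float:
    """Item surrogate from the 2 x G artificial data:
    sum_g [ r_g log F_g + (f_g - r_g) log(1 - F_g) ] - eta ||a_j||_1."""
    logF, log1mF = _item_logprobs(a_j, b_j, grid.points)
    val = float(w_j[1] @ logF + w_j[0] @ log1mF)
    return val - eta * np.abs(a_j).sum()


def qj_naive(
    a_j: np.ndarray,
    b_j: float,
    y_col: np.ndarray,
    post: PosteriorTable,
    grid: GridSet,
    eta: float = 0.0,
) -> float:
    """Item surrogate in the naive N x G augmented-data form:
    sum_i sum_g [ y_ij log F_g + (1 - y_ij) log(1 - F_g) ] p(theta^(g)|y_i) - eta ||a_j||_1.

    ``y_col`` is the item's column of the *original* (ungrouped) Y; pattern
    multiplicities in the table are honored through the inverse index.
    """
    logF, log1mF = _item_logprobs(a_j, b_j, grid.points)
    w_rows = post.weights[post.inverse]  # (N, G)
    y = np.asarray(y_col, dtype=float)
    per_subject = w_rows @ logF * y + w_rows @ log1mF * (1.0 - y)
    return float(per_subject.sum()) - eta * np.abs(a_j).sum()


def qj_value(a_j, b_j, mode: str, eta: float = 0.0, **inputs) -> float:
    """Dispatch to the naive or weighted item-surrogate evaluation.

    ``mode='weighted'`` expects ``w_j`` and ``grid``; ``mode='naive'``
    expects ``y_col``, ``post`` and ``grid``.  Both return identical values
    for E-step-consistent inputs (the regrouping identity).
    """
    if mode == "weighted":
        return qj_weighted(a_j, b_j, inputs["w_j"], inputs["grid"], eta)
    if mode == "naive":
        return qj_naive(a_j, b_j, inputs["y_col"], inputs["post"], inputs["grid"], eta)
    raise ValueError(f"unknown mode {mode!r}")


def q_components(
    params: ItemParams,
    sigma: LatentCov,
    art: ArtificialData,
    S_star: np.ndarray,
    grid: GridSet,
    N: int,
    eta: float = 0.0,
) -> QComponents:
    """Evaluate the full surrogate Q0 + sum_j Qj at the given parameters."""
    q0 = q0_value(sigma, S_star, N)
    qj = np.array(
        [qj_weighted(params.A[j], params.b[j], art.w[j], grid, eta) for j in range(params.J)]
    )
    return QComponents(q0=q0, qj=qj)
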