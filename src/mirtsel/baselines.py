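"""Baseline estimators: constrained exploratory IFA and hard-threshold variants.

EIFAthr estimates all parameters by an unpenalized constrained exploratory
item factor analysis (the anchor identification constraints are kept) and
then truncates loadings below a fixed cutoff to zero.  EIFAopt picks the
cutoff from a candidate list by minimum BIC, re-evaluating the likelihood
at each truncated parameter set.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .em_driver import FitResult, bic, em_fit
from .model_core import ItemParams, ModelConfig, ResponseMatrix, loading_structure
from .quadrature import GridSet

__all__ = ["constrained_eifa", "hard_threshold_estimate", "eifa_opt", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.30, 0.7001, 0.05), 2))


def constrained_eifa(Y: ResponseMatrix, config: ModelConfig, grid: GridSet,
                     **em_kwargs) -> FitResult:
    """Unpenalized (eta = 0) constrained exploratory fit with Sigma estimated."""
    return em_fit(Y, 0.0, config, grid, variant="ieml1", **em_kwargs)


def hard_threshold_estimate(A_hat: np.ndarray, c: float, config: ModelConfig):
    """Zero every free loading with |a_jk| < c; anchor loadings are exempt.

    Returns the truncated loading matrix and its binary structure.
    """
    if c < 0:
        raise ValueError("threshold must be non-negative")
    A = np.asarray(A_hat, dtype=float).copy()
    exempt = np.zeros_like(A, dtype=bool)
    for j, k in config.anchor_map.items():
        exempt[j, k] = True
    A[(np.abs(A) < c) & ~exempt] = 0.0
    Lambda = loading_structure(ItemParams(A, np.zeros(A.shape[0])))
    return A, Lambda


def eifa_opt(
    Y: ResponseMatrix,
    config: ModelConfig,
    grid: GridSet,
    thresholds=DEFAULT_THRESHOLDS,
    base_fit: FitResult | None = None,
    **em_kwargs,
) -> FitResult:
    """EIFA with the BIC-optimal hard threshold.

    One constrained exploratory fit, then per-threshold truncation with the
    likelihood re-evaluated at the truncated parameters; the minimum-BIC
    truncation wins (ties toward the larger, sparser threshold).
    """
    thresholds = np.asarray(sorted(thresholds, reverse=True), dtype=float)
    if thresholds.size == 0:
        raise ValueError("thresholds must be non-empty")
    fit = base_fit if base_fit is not None else constrained_eifa(Y, config, grid, **em_kwargs)
    best = None
    for c in thresholds:
        A_c, Lambda_c = hard_threshold_estimate(fit.params.A, c, config)
        params_c = ItemParams(A_c, fit.params.b.copy())
        bic_c = bic(params_c, fit.sigma, Y, grid, config, sigma_estimated=True)
        if best is None or bic_c < best.bic:
            best = replace(fit, params=params_c, Lambda=Lambda_c, bic=bic_c,
                           threshold=float(c))
    return best
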