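"""Evaluation metrics for latent variable selection and parameter recovery.

All structure metrics are computed over the *free* entries only: the K
anchor rows are excluded, since their pattern is fixed by the
identification constraints, leaving K(J - K) comparable entries.  The
correct rate (CR) is the proportion of those entries whose zero/non-zero
status is recovered; FNR/FPR/precision treat a truly non-zero loading as
the positive class.  MSEs are per-parameter averages of squared errors
across replications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import LoadingStructure, ModelConfig

__all__ = ["MetricReport", "correct_rate", "confusion_metrics", "mse_report"]


@dataclass
class MetricReport:
    """Per-parameter MSE maps and optional structure-recovery proportions."""

    mse_A: np.ndarray
    mse_b: np.ndarray
    mse_Sigma: np.ndarray
    cr: float | None = None
    fnr: float | None = None
    fpr: float | None = None
    precision: float | None = None


def _free_row_mask(config: ModelConfig, J: int) -> np.ndarray:
    mask = np.ones(J, dtype=bool)
    for j in config.anchor_map:
        mask[j] = False
    return mask


def _as_array(L) -> np.ndarray:
    return L.Lambda if isinstance(L, LoadingStructure) else np.asarray(L)


def correct_rate(Lambda_hat, Lambda_true, config: ModelConfig) -> float:
    """Proportion of non-anchored structure entries recovered exactly;
    the denominator is K(J - K)."""
    Lh, Lt = _as_array(Lambda_hat), _as_array(Lambda_true)
    if Lh.shape != Lt.shape:
        raise ValueError("structure shapes disagree")
    rows = _free_row_mask(config, Lh.shape[0])
    return float((Lh[rows] == Lt[rows]).mean())


def confusion_metrics(Lambda_hat, Lambda_true, config: ModelConfig):
    """(FNR, FPR, precision) over non-anchored entries; positives are true
    non-zero loadings.  A zero denominator yields NaN for that ratio."""
    Lh, Lt = _as_array(Lambda_hat), _as_array(Lambda_true)
    rows = _free_row_mask(config, Lh.shape[0])
    h, t = Lh[rows].astype(bool), Lt[rows].astype(bool)
    tp = int((h & t).sum())
    fn = int((~h & t).sum())
    fp = int((h & ~t).sum())
    tn = int((~h & ~t).sum())
    fnr = fn / (fn + tp) if (fn + tp) else float("nan")
    fpr = fp / (fp + tn) if (fp + tn) else float("nan")
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    return fnr, fpr, precision


def mse_report(estimates, truth) -> MetricReport:
    """Per-entry mean squared errors over S replications.

    ``estimates`` is a sequence of (A_hat, b_hat, Sigma_hat) triples (or
    FitResult-like objects exposing ``params`` and ``sigma``); ``truth``
    exposes ``A``, ``b`` and ``Sigma``.  The Sigma map covers the free
    off-diagonal entries (the diagonal is fixed at one).
    """
    A_list, b_list, S_list = [], [], []
    for est in estimates:
        if hasattr(est, "params"):
            A_list.append(est.params.A)
            b_list.append(est.params.b)
            S_list.append(est.sigma.Sigma)
        else:
            A_hat, b_hat, S_hat = est
            A_list.append(np.asarray(A_hat))
            b_list.append(np.asarray(b_hat))
            S_list.append(np.asarray(S_hat))
    if not A_list:
        raise ValueError("need at least one replication")
    A_true = np.asarray(truth.A, dtype=float)
    b_true = np.asarray(truth.b, dtype=float)
    S_true = np.asarray(truth.Sigma, dtype=float)
    mse_A = np.mean([(A - A_true) ** 2 for A in A_list], axis=0)
    mse_b = np.mean([(b - b_true) ** 2 for b in b_list], axis=0)
    mse_S = np.mean([(S - S_true) ** 2 for S in S_list], axis=0)
    np.fill_diagonal(mse_S, 0.0)
    return MetricReport(mse_A=mse_A, mse_b=mse_b, mse_Sigma=mse_S)
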