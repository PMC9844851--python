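"""Reading response matrices and writing fit artifacts.

Responses are a CSV with one subject per row and one 0/1 cell per item;
an optional header row carries item labels.  Fits are written as TSVs
(loading matrix, difficulties, covariance, structure), a per-eta path
CSV, and a run.json with configuration, seed and convergence diagnostics.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .em_driver import FitResult, TuningPath
from .model_core import ResponseMatrix

__all__ = ["read_responses", "write_fit", "expand_eta_preset"]

_FMT = "%.17g"

# standard tuning grids as multiples of the sample size N
ETA_PRESETS = {
    "sim": np.round(np.arange(0.10, 0.0099, -0.01), 2),
    "real": np.round(np.arange(0.040, 0.0019, -0.002), 3),
}


def expand_eta_preset(preset, N: int) -> np.ndarray:
    """Expand a named preset ('sim', 'real') or explicit list to absolute etas."""
    if isinstance(preset, str):
        try:
            fracs = ETA_PRESETS[preset]
        except KeyError:
            raise ValueError(f"unknown eta preset {preset!r}; known: {sorted(ETA_PRESETS)}")
        return fracs * N
    return np.asarray(preset, dtype=float)


def read_responses(path) -> tuple[ResponseMatrix, list[str] | None]:
    """Read a binary response CSV; returns the matrix and item labels (or None).

    A non-numeric first row is treated as a header of item labels.  Any
    ragged row, missing value or non-binary cell raises with its location.
    """
    path = Path(path)
    head = pd.read_csv(path, header=None, nrows=1)
    has_header = not all(str(v).strip() in ("0", "1") for v in head.iloc[0])
    df = pd.read_csv(path, header=0 if has_header else None)
    labels = [str(c) for c in df.columns] if has_header else None
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(f"missing value at data row {r}, column {c} of {path}")
    arr = df.to_numpy()
    bad = np.argwhere(~np.isin(arr, (0, 1)))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-binary entry {arr[r, c]!r} at data row {r}, column {c} of {path}"
        )
    return ResponseMatrix(arr.astype(np.int8)), labels


def _save(path: Path, arr: np.ndarray, labels=None) -> None:
    np.savetxt(path, np.atleast_2d(arr), fmt=_FMT, delimiter="\t")


def write_fit(
    fit: FitResult,
    outdir,
    path: TuningPath | None = None,
    config: dict | None = None,
    seed: int | None = None,
    labels: list[str] | None = None,
) -> None:
    """Write A.tsv, b.tsv, sigma.tsv, lambda.tsv, optional path.csv, run.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _save(outdir / "A.tsv", fit.params.A)
    _save(outdir / "b.tsv", fit.params.b[:, None])
    _save(outdir / "sigma.tsv", fit.sigma.Sigma)
    np.savetxt(outdir / "lambda.tsv", fit.Lambda.Lambda, fmt="%d", delimiter="\t")
    if path is not None:
        rows = []
        for eta, f in zip(path.etas, path.fits):
            if f is None:
                rows.append({"eta": eta, "bic": np.nan, "n_nonzero": -1,
                             "n_iter": -1, "converged": False})
            else:
                rows.append(
                    {
                        "eta": eta,
                        "bic": f.bic,
                        "n_nonzero": int(np.count_nonzero(f.params.A)),
                        "n_iter": f.n_iter,
                        "converged": f.converged,
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "path.csv", index=False)
    run = {
        "eta": fit.eta,
        "bic": fit.bic,
        "n_iter": fit.n_iter,
        "converged": fit.converged,
        "sigma_known": fit.sigma_known,
        "kkt": fit.kkt,
        "warnings": list(fit.warnings),
        "seed": seed,
        "config": config,
        "item_labels": labels,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    (outdir / "run.json").write_text(json.dumps(run, indent=2, default=str))
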