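"""Synthetic M2PL data generation and weight-concentration diagnostics.

The default study design: J = 40 items measuring K in {3, 4, 5} latent
traits; non-zero discriminations drawn i.i.d. U(0.5, 2); difficulties
i.i.d. N(0, 1); latent covariance with unit diagonal and all off-diagonal
entries 0.1.  One anchor item per trait resolves rotational
indeterminacy; the anchor positions depend on K (items 1, 10, 19 for
K = 3; 1, 7, 13, 19 for K = 4; 1, 5, 9, 13, 17 for K = 5, 1-based).

The default loading structure is block-sparse: a contiguous block of
single-trait items starts at each anchor, and the remaining items load on
two adjacent traits, giving roughly equal items per trait.  Any
user-supplied binary J x K pattern consistent with the anchors is
accepted instead.

``weight_diagnostics`` supports the reduced-grid heuristic: the 2 x G
artificial-data weights of an item, sorted in descending order, typically
concentrate on a small fraction of grid points well inside the nominal
[-4, 4]^K cube, which motivates the 7- or 5-point grids on [-2.4, 2.4].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .estep import ArtificialData
from .model_core import ItemParams, LatentCov, ModelConfig, ResponseMatrix, loading_structure
from .quadrature import GridSet

__all__ = [
    "ANCHOR_ITEMS",
    "SimConfig",
    "TrueModel",
    "default_structure",
    "generate_true_model",
    "generate_responses",
    "WeightDiagnostics",
    "weight_diagnostics",
]

# 0-based anchor item indices per trait count
ANCHOR_ITEMS = {
    3: (0, 9, 18),
    4: (0, 6, 12, 18),
    5: (0, 4, 8, 12, 16),
}


@dataclass(frozen=True)
class SimConfig:
    """Design of one synthetic study condition."""

    N: int
    J: int = 40
    K: int = 3
    off_diag: float = 0.1
    structure: np.ndarray | str = "default"
    seed: int = 0

    @property
    def anchor_map(self) -> dict[int, int]:
        if self.K in ANCHOR_ITEMS and self.J > max(ANCHOR_ITEMS[self.K]):
            return {j: k for k, j in enumerate(ANCHOR_ITEMS[self.K])}
        # fall back to the first K items for non-standard designs
        return {k: k for k in range(self.K)}

    def model_config(self) -> ModelConfig:
        return ModelConfig(N=self.N, J=self.J, K=self.K, anchor_map=self.anchor_map)


@dataclass
class TrueModel:
    """A fully specified generating model, serializable to JSON."""

    A: np.ndarray
    b: np.ndarray
    Sigma: np.ndarray
    anchor_map: dict[int, int]
    seed: int

    @property
    def Lambda(self) -> np.ndarray:
        return (self.A != 0).astype(np.int8)

    def item_params(self) -> ItemParams:
        return ItemParams(self.A.copy(), self.b.copy())

    def latent_cov(self) -> LatentCov:
        return LatentCov(self.Sigma.copy())

    def to_json(self) -> str:
        return json.dumps(
            {
                "A": self.A.tolist(),
                "b": self.b.tolist(),
                "Sigma": self.Sigma.tolist(),
                "anchor_map": {str(j): k for j, k in self.anchor_map.items()},
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TrueModel":
        d = json.loads(text)
        return cls(
            A=np.array(d["A"], dtype=float),
            b=np.array(d["b"], dtype=float),
            Sigma=np.array(d["Sigma"], dtype=float),
            anchor_map={int(j): int(k) for j, k in d["anchor_map"].items()},
            seed=int(d["seed"]),
        )


def default_structure(J: int, K: int, anchor_map: dict[int, int]) -> np.ndarray:
    """Block-sparse binary pattern: a contiguous single-trait block starts
    at each anchor; remaining items load on two adjacent traits."""
    anchors = sorted(anchor_map, key=lambda j: anchor_map[j])
    Lambda = np.zeros((J, K), dtype=np.int8)
    gap = anchors[1] - anchors[0] if K > 1 else J
    for k, j0 in enumerate(anchors):
        Lambda[j0 : j0 + gap, k] = 1
    start = anchors[-1] + gap
    for m, j in enumerate(range(start, J)):
        k = m % K
        Lambda[j, k] = 1
        Lambda[j, (k + 1) % K] = 1
    return Lambda


def generate_true_model(cfg: SimConfig) -> TrueModel:
    """Draw a generating model under the study design (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    anchor_map = cfg.anchor_map
    if isinstance(cfg.structure, str):
        Lambda = default_structure(cfg.J, cfg.K, anchor_map)
    else:
        Lambda = np.asarray(cfg.structure, dtype=np.int8)
        if Lambda.shape != (cfg.J, cfg.K):
            raise ValueError("structure must be J x K")
        for j, k in anchor_map.items():
            row = np.zeros(cfg.K, dtype=np.int8)
            row[k] = 1
            if not np.array_equal(Lambda[j], row):
                raise ValueError(f"structure row {j} conflicts with its anchor constraint")
    A = np.zeros((cfg.J, cfg.K))
    nz = Lambda.astype(bool)
    A[nz] = rng.uniform(0.5, 2.0, size=int(nz.sum()))
    b = rng.standard_normal(cfg.J)
    Sigma = np.full((cfg.K, cfg.K), cfg.off_diag)
    np.fill_diagonal(Sigma, 1.0)
    return TrueModel(A=A, b=b, Sigma=Sigma, anchor_map=dict(anchor_map), seed=cfg.seed)


def generate_responses(model: TrueModel, N: int, seed: int) -> ResponseMatrix:
    """Draw theta_i ~ N(0, Sigma) and y_ij ~ Bernoulli(expit(a_j' theta_i + b_j))."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(model.Sigma)
    theta = rng.standard_normal((N, model.Sigma.shape[0])) @ L.T
    from scipy.special import expit

    P = expit(theta @ model.A.T + model.b)
    Y = (rng.random(P.shape) < P).astype(np.int8)
    return ResponseMatrix(Y)


@dataclass
class WeightDiagnostics:
    """Sorted artificial-data weights of one item with concentration curves.

    ``sorted_weights`` are the 2G weights in descending order (their total
    equals N); ``cumulative_fraction`` the running share of the total;
    ``points`` the grid point of each sorted weight.
    """

    sorted_weights: np.ndarray
    cumulative_fraction: np.ndarray
    points: np.ndarray

    def top_share(self, m: int) -> float:
        """Fraction of the total weight carried by the m largest weights."""
        m = min(m, self.sorted_weights.size)
        if m <= 0:
            return 0.0
        return float(self.cumulative_fraction[m - 1])

    def bounding_halfwidth(self, m: int) -> float:
        """Smallest c such that [-c, c]^K contains the grid points of the
        top-m weights — the basis for choosing a reduced grid interval."""
        m = min(m, self.points.shape[0])
        return float(np.abs(self.points[:m]).max())


def weight_diagnostics(art: ArtificialData, grid: GridSet, item: int) -> WeightDiagnostics:
    """Concentration diagnostics of the 2 x G artificial weights for one item."""
    if not (0 <= item < art.J):
        raise IndexError(f"item {item} out of range")
    w = art.w[item].ravel()  # (2G,) — z = 0 block then z = 1 block
    pts = np.vstack([grid.points, grid.points])
    order = np.argsort(w)[::-1]
    sw = w[order]
    total = sw.sum()
    cum = np.cumsum(sw) / total
    return WeightDiagnostics(sorted_weights=sw, cumulative_fraction=cum, points=pts[order])
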