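# mirtsel

**Sparse latent variable selection for multidimensional item response
models, via an accelerated L1-penalized EM algorithm.**

## The problem

Psychological and health questionnaires measure several latent traits at
once: which items measure which traits? In the multidimensional
two-parameter logistic (M2PL) model, subject *i*'s binary response to item
*j* follows

    P(y_ij = 1 | θ_i) = expit(a_j' θ_i + b_j),      θ_i ~ N(0, Σ),

with discriminations a_j ∈ R^K, difficulty b_j, and a unit-diagonal latent
covariance Σ. Item *j* measures trait *k* exactly when a_jk ≠ 0, so the
item–trait structure is the support Λ of the J×K loading matrix A.
`mirtsel` estimates (A, b, Σ) and selects Λ by maximizing the L1-penalized
marginal log-likelihood

    l(A, b, Σ | Y) − η‖A‖₁,

with Σ treated as unknown and updated inside the EM loop, and the penalty
weight η tuned by BIC. A handful of anchor items (each pinned to a single
pre-assigned trait) resolves rotational indeterminacy.

The EM's E-step discretizes the latent posterior on a fixed quadrature
grid and collapses the N×G augmented observations into **2×G artificial
observations per item** — expected response frequencies at each ability
level — which shrinks each M-step from O(N·G) to O(2·G) without changing
the estimator (the two formulations are algebraically identical, and the
package verifies their fitted values agree to ~1e-13). M-steps solve
weighted L1-penalized logistic regressions by coordinate descent with
soft-thresholding, plus a projected-gradient update of Σ constrained to
unit diagonal. Grids of 11 points per dimension on [−4, 4] or the reduced
7/5-point grids on [−2.4, 2.4] (motivated by the concentration of the
artificial-data weights) are built in.

Intended users: psychometricians and applied statisticians doing
exploratory item factor analysis on dichotomous response data who want a
sparse, rotation-free loading structure with an estimated latent
covariance.

## Worked example

Simulate a 10-item, two-trait test, tune the penalty by BIC, and score the
recovered structure against the generating truth:

```python
import numpy as np
import mirtsel as m

struct = np.array([[1, 0], [0, 1], [1, 0], [1, 0], [1, 0],
                   [0, 1], [0, 1], [0, 1], [1, 1], [1, 1]])
sim = m.SimConfig(N=500, J=10, K=2, seed=3, structure=struct)
model = m.generate_true_model(sim)              # A ~ U(0.5,2) on struct, b ~ N(0,1)
Y = m.generate_responses(model, 500, seed=4)    # 500 x 10 binary matrix

cfg = sim.model_config()                        # anchors: item 1 -> trait 1, item 2 -> trait 2
grid = m.build_grid(5, (-2.4, 2.4), 2)          # 25 quadrature points
etas = m.expand_eta_preset("sim", 500)          # (0.10, ..., 0.01) x N
path = m.fit_path(Y, etas, cfg, grid)           # 10 fits, BIC-selected
best = path.best

print("selected eta:", best.eta)
print("estimated structure:\n", best.Lambda.Lambda)
print("correct rate:", m.correct_rate(best.Lambda, model.Lambda, cfg))
print("Sigma_12: estimate %.3f  truth %.3f" % (best.sigma.Sigma[0, 1], model.Sigma[0, 1]))
```

Output:

```
selected eta: 10.0
estimated structure:
 [[1 0]
 [0 1]
 [1 0]
 [1 0]
 [1 0]
 [0 1]
 [0 1]
 [0 1]
 [1 0]
 [1 1]]
correct rate: 0.9375
Sigma_12: estimate 0.195  truth 0.100
```

The BIC-selected penalty η = 0.02·N recovers 15 of the 16 non-anchored
structure entries (item 9's weaker second loading is missed at this sample
size — correct rate 0.9375), and the latent correlation is estimated from
the same penalized fit rather than plugged in from a separate stage. At
the N = 1000 study scale the mean correct rate exceeds 0.9 (see the
acceptance script below).

The same pipeline is available from the shell:

```bash
mirtsel simulate --n 500 --j 10 --k 2 --seed 3 --out sim/
mirtsel fit sim/Y.csv --config cfg.json --out fit/
mirtsel evaluate fit/ sim/truth.json --k 2
```

plus `mirtsel baselines` (two-stage, EIFAthr, EIFAopt) and
`mirtsel diagnose-grid` (artificial-weight concentration and a recommended
reduced grid box). See `docs/methods.md` for the algorithmic details and
design choices.

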