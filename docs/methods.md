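# Methods

## Model

`mirtsel` estimates the multidimensional two-parameter logistic (M2PL) item
response model for binary data. Subject *i* holds a latent trait vector
θ\_i ∈ R^K with θ\_i ~ N(0, Σ), Σ a unit-diagonal covariance (a correlation
matrix). Given θ\_i, responses are conditionally independent with

    P(y_ij = 1 | θ_i) = F_j(θ_i) = expit(a_j' θ_i + b_j),

where a\_j ∈ R^K are the item's discriminations (the j-th row of the J×K
loading matrix A) and b\_j its difficulty/intercept. Latent variable
selection asks which a\_jk are non-zero; the binary support Λ = (I(a\_jk ≠ 0))
is the scientific object of interest.

Identification: trait variances are fixed at one, and a small set of
*anchor items* is constrained to load on exactly one pre-assigned trait
each (all their other loadings pinned at exact zero). Anchors fix the
rotation and scale of the latent space but not the sign of each axis; after
a fit with estimated Σ, any trait whose anchor loading converged negative
has its loading column and the corresponding Σ row/column sign-flipped.
With a user-supplied fixed Σ no flip is applied, because the flip would
have to alter Σ.

## Objective

Estimation maximizes the L1-penalized marginal log-likelihood

    l(A, b, Σ | Y) − η ‖A‖₁,

with ‖A‖₁ the entrywise L1 norm over all free loadings (anchor loadings
included; structurally fixed zeros are excluded from optimization
entirely) and b unpenalized. The marginal likelihood integral over θ is
replaced by a sum over a fixed quadrature grid — a K-ary Cartesian power of
equally spaced points. `observed_loglik` treats the normal prior as
*discretized on the grid* (normalized over the grid points), so that a
model with constant response probabilities has exactly the likelihood of
the corresponding Bernoulli products, independent of the grid.

Default grids: 11 points per dimension on [−4, 4] ("Grid11") for
reference-quality runs, 7 or 5 points per dimension on [−2.4, 2.4]
("Grid7"/"Grid5") as fast defaults for K ≤ 5. The reduced intervals are
justified empirically: after one EM iteration on a standard design, the
largest artificial-data weights concentrate well inside the nominal cube
(the package's weight diagnostics reproduce this), so wide tails mostly pay
for quadrature nodes with negligible posterior mass. Three points per
dimension is accepted but warned against — the discretized posterior
moments become too coarse (the package warns below 5 points per
dimension).

## EM algorithm

Each iteration computes the discrete posterior p̃(θ^(g) | y\_i) ∝
φ(θ^(g)|Σ) Π\_j F\_j^{y\_ij} (1−F\_j)^{1−y\_ij} over grid points (log-space
accumulation throughout; J = 40 Bernoulli factors underflow linear
arithmetic long before they stop mattering). Subjects sharing a response
pattern share a posterior, so the table is computed per *distinct* pattern
with multiplicities.

The expected complete-data log-likelihood separates into a covariance part
Q₀ and per-item parts Q\_j. The accelerated variant collapses the N×G
augmented observations of Q\_j into 2×G *artificial observations*
(z, θ^(g)), z ∈ {0,1}, with weights

    w_j(z, θ^(g)) = Σ_i I(y_ij = z) p̃(θ^(g) | y_i),

an exact regrouping (tested to 1e-12) that reduces the per-item M-step
cost from O(NG) to O(2G). The classical expected counts appear as
f\_g = Σ\_i p̃(θ^(g)|y\_i) and r\_jg = Σ\_i y\_ij p̃(θ^(g)|y\_i), with
w\_j(1,·) = r\_j and w\_j(0,·) = f − r\_j. The naive variant (`eml1_naive`)
solves the same M-step on the full N×G rows; both variants maximize the
identical surrogate, and when both are run to their numerical fixed point
their estimates agree to ~1e-13 (the package's equivalence check).

### Item M-step

Each item solves a weighted L1-penalized logistic regression on its
pseudo-observations by iteratively reweighted least squares with
coordinate-wise soft-thresholding on the weighted quadratic surrogate.
Numerical choices:

- curvature per pseudo-row uses the exact logistic variance w·p(1−p)
  (clipped below at 1e-10 to keep the working denominators finite), not
  the 1/4 bound — faster at the small pseudo-sample sizes involved;
- coordinates are swept in fixed order (loadings 1..K, then the
  unpenalized intercept), so runs are bitwise reproducible;
- the inner coordinate loop stops when the largest coefficient change
  falls below `inner_tol` (default 1e-10); the IRLS step is accepted with
  per-item step-halving whenever the true objective would otherwise
  decrease (comparisons are noise-guarded at ~1e-12 relative, since item
  objectives are O(N));
- an item is finished when one IRLS step no longer moves it by more than
  10×`inner_tol`;
- inactive penalized coordinates land on *exact* zeros (the support is
  read off directly, no thresholding);
- complete separation in the pseudo-responses (all mass in one class)
  clips the intercept at ±30 with a warning.

All J items advance in lock-step as (J, G) array operations
(`fit_items_weighted_l1_multi`); a single-item solver with identical
mathematics (`fit_weighted_logistic`) backs the naive variant and the unit
tests, which verify KKT subgradient conditions at 1e-6 per coordinate.

### Covariance M-step

Maximizing Q₀(Σ) = −N/2 {K log 2π + log det Σ + tr(Σ⁻¹ S\*)} over
unit-diagonal positive-definite Σ, with S\* the posterior second-moment
matrix, is done by projected gradient ascent with backtracking: the
gradient is projected onto the tangent space of the diagonal constraint
(diagonal zeroed), trial points are mapped to the feasible set by
symmetrization, eigenvalue clipping at 1e-6 and D^{−1/2} M D^{−1/2}
rescaling, and steps are accepted only if Q₀ increases (monotone by
construction). The subproblem is run to stationarity (projected gradient
max-norm < 1e-6 on the N-free scale) within each M-step. For a
unit-diagonal S\* with off-diagonal s at K = 2 the update provably returns
Σ₁₂ = s; the tests confirm this against a one-dimensional grid search.

### Convergence and monotonicity

The EM stops when the max elementwise change in (A, b) falls below
`tol_param` (default 1e-5) *and* the relative change of the penalized
objective falls below `tol_obj` (default 1e-8), or at `max_iter` = 500.
Σ is deliberately excluded from the parameter-change criterion: in
quadrature-degenerate directions (e.g. under fully shrunk loadings, where
the likelihood is flat in Σ) the constrained update can creep
geometrically for thousands of iterations without a likelihood-relevant
change; Σ's meaningful movement is captured by the objective term.

The recorded per-iteration trace is the penalized marginal objective of
the grid-discretized model with the *unnormalized* prior mass, for which
EM ascent is mathematically exact (including the Σ update); a surrogate
decrease beyond 1e-6 aborts the run loudly. The default solver tolerances
are tighter than typical GLM practice because the cross-variant
equivalence check works at the 1e-13 level; the equivalence runs
themselves use machine-tight settings (`inner_tol` 1e-13, `tol_param`
1e-14) to drive both variants to the shared fixed point.

## Penalty tuning

The tuning grids are (0.10, 0.09, …, 0.01) × N for simulation-scale
problems and (0.040, 0.038, …, 0.002) × N for the questionnaire protocol.
Model selection uses BIC with d = (# non-zero loadings) + J + K(K−1)/2
(the Σ count only when Σ is estimated).

Two deliberate choices, both visible in the code:

1. **BIC is evaluated on a support-restricted ML refit.** BIC computed at
   the shrunk estimates is dominated by shrinkage bias: the likelihood
   loss from biasing ~50 true loadings costs far more than log N per
   spurious loading, so the criterion degenerates into always preferring
   the smallest η. Scoring each candidate *structure* by the BIC of an
   unpenalized EM refit restricted to its support (duplicate supports
   refit once, warm-started from the penalized solution) restores an
   interior minimum and selects structures rather than shrinkage levels.
   The penalized fit at the selected η remains the reported estimate;
   `FitResult.bic` keeps the at-the-estimate value and
   `FitResult.bic_refit` the selection criterion.
2. **Path fits are cold-started by default.** The penalized marginal
   problem is non-convex. The fully shrunk point (A = 0 with b at the
   flat-model logits) is a stationary point of the EM map at *every* η —
   with A = 0 the posterior equals the prior and every item score
   vanishes — so warm-starting a smaller η from a fully (or heavily)
   shrunk solution can silently stay in the wrong basin. Restarting each
   η from the standard initialization matches the protocol of fixing the
   initial values for every run; `warm_start=True` remains available and
   nudges zeroed loadings back to their default initial values.

Ties in BIC select the larger η (sparser structure). The default
initialization is: anchor loadings 1 (an identity block), all other free
loadings 1/J, b = 0, Σ = I.

## Baselines

- **Constrained exploratory IFA**: the same EM at η = 0 with Σ estimated
  (no exact sparsity results — unpenalized ML keeps every free loading
  non-zero).
- **EIFAthr**: hard-threshold the exploratory loadings at a fixed cutoff
  (anchor loadings exempt).
- **EIFAopt**: pick the cutoff from (0.30, 0.35, …, 0.70) by BIC, with the
  likelihood re-evaluated at the truncated parameters.
- **Two-stage**: estimate Σ by the exploratory fit, then run the penalized
  path with Σ fixed at that estimate.

The exploratory stage is this package's own EM, not a re-implementation of
any external IFA program's numerics; only structural behavior is
comparable.

## Synthetic data

The generator reproduces the standard study design: J = 40 items, K ∈
{3, 4, 5} traits; non-zero discriminations i.i.d. U(0.5, 2); difficulties
i.i.d. N(0, 1); Σ with unit diagonal and all off-diagonals 0.1; anchor
items (1, 10, 19), (1, 7, 13, 19) or (1, 5, 9, 13, 17) (1-based) for
K = 3, 4, 5. The default loading pattern is block-sparse: a contiguous
block of single-trait items starts at each anchor, and the remaining items
load on two adjacent traits — roughly equal items per trait, with genuine
cross-loading items to make the selection problem non-trivial. Any
user-supplied binary pattern consistent with the anchors is accepted.
Each replication derives its model and response seeds from a master seed
by fixed offsets.

What the generator does **not** emulate: missing responses, guessing
(3PL/4PL behavior), non-normal or dependent latent traits, local item
dependence, and any specific published item bank. Passing recovery tests
therefore demonstrate the estimator's behavior under the stated design,
not performance guarantees on real questionnaires.

## Study sizes used by the tests and the acceptance script

Replication studies are sized to run on one CPU in minutes: the recovery
study uses 8 (test suite) or 10 (acceptance script) replications at
N = 1000, K = 3 on the 5-point grid, and the grid-robustness comparison 3
or 4 replications at N = 500 across the 11-, 7- and 5-point grids. The
qualitative findings these runs check — mean correct rate ≥ 0.9, the
penalized estimator beating the two-stage plug-in on Σ accuracy, and mean
correct rates agreeing within 0.05 across grids — are stable across seeds
at these sizes.

## Known limitations

- The estimator handles complete 0/1 response matrices only; rows with
  missing entries must be removed or imputed upstream.
- Fixed rectangular quadrature scales exponentially in K; K > 5 is
  impractical without the reduced grids, and the artificial-data
  construction is incompatible with adaptive quadrature or Monte Carlo
  E-steps (each subject would need its own node set).
- BIC degrees of freedom for this penalized, anchored model are a
  convention, not a theorem; the d above is declared and configurable in
  spirit (the pieces are exposed), and selection behavior, not the
  absolute BIC value, is what the package relies on.
- Constant response columns leave the corresponding item parameters
  unidentified (warned, not repaired).
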