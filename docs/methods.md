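# Methods

## Model

Phenotypes follow a linear (or logistic) model on a low-dimensional latent
structure of the expression matrix.  The generative model behind both the
method's assumptions and the synthetic-data generator is an orthogonal
factor model:

```
x_i = u_iᵀ Λ_d V_dᵀ + σ_x e_i,    u_i ~ N(0, I_d),  e_i ~ N(0, I_p)
y_i = u_iᵀ Θ + σ_y z_i,           z_i ~ N(0, 1)
```

with V_d ∈ R^{p×d}, V_dᵀV_d = I_d, row sparse: only s rows are nonzero.
Then Σ = V L Vᵀ with eigenvalues l_i = λ_i² + σ_x² for i ≤ d and σ_x²
otherwise, the marginal covariance is Φ = V_d Λ_d Θ, and the population
coefficient is β* = V_d L_d⁻¹ Λ_d Θ — supported exactly on the nonzero
rows of V_d.  The estimator targets that support and the prediction it
carries.

Assumptions that matter in practice: the leading subspace is genuinely
low-dimensional (d small and known — d is a user input, as in standard
PCR practice), its loadings are row sparse, and features are standardized
so the covariance is a correlation matrix.  Nothing requires Φ_j ≠ 0 for
relevant features — that is the point.

## Estimation pipeline

1. Columns of X are centered and scaled by population (1/n) standard
   deviations so S = (1/n)XsᵀXs has unit diagonal; zero-variance features
   are dropped and reported, never scaled by zero.  y is centered
   (Gaussian family).
2. The Fantope relaxation `max tr(SP) − λ‖P‖₁,₁, P ∈ F^d` is solved by
   ADMM with the penalty parameter tied to λ (the data enter as S/λ and
   the soft-threshold level is 1).  The Fantope projection modifies only
   the eigenvalues: clip(eig − τ, [0, 1]) with τ solving
   Σ clip = d (bisection on [min − 1, max] to 1e-12; the map is monotone
   piecewise-linear, so any point of a flat solution interval gives the
   same projection).
3. The top-d eigenvectors of the sparse iterate are extracted
   (deterministic sign: largest-magnitude entry positive), row energies
   l_j = ‖v_j‖² are sorted descending, and the elbow index i* is the first
   i ≥ 3 where the jump in the empirical derivative of
   T[i] = i·var(l[1..i]) + (p−i)·var(l[i+1..p]) exceeds the running mean
   of |δ|.  Rows with energy strictly below t = l[i*] are zeroed.  Because
   t equals a profile value, the single boundary row survives the strict
   comparison; on profiles where the iterate is already row sparse the
   rule returns t = 0 and the support is just the nonzero rows.
4. γ̂ is OLS of the centered response on the derived components Xs V̂_d
   (unpenalized logistic regression for binary labels, lbfgs with a
   200-iteration cap; perfect separation of the d-dimensional scores is
   detected and flagged), and β̂ = V̂_d γ̂.

## Solver details

* **Truncated projection.**  Only the top-k eigenpairs are computed
  (ARPACK, deterministic warm start), k grown from max(2d, d+10) by
  doubling until the smallest retained clipped eigenvalue is exactly zero
  — the certificate that omitted eigenpairs contribute nothing.  When 2k
  exceeds p/8 the spectrum near the clip level is crowded and one dense
  decomposition is cheaper than further partial solves, so the
  implementation falls through to it (and skips partial attempts for the
  next 24 iterations after a dense fall-through).  Across ADMM iterations
  the previous eigenvector block warm-starts a LOBPCG solve (≤ 10
  iterations, residual acceptance 2e-6·|w|max) and the truncation width
  tracks the active spectrum.  In-loop eigensolver tolerance is 1e-6;
  standalone projections use machine precision.  Truncated and dense
  projections agree entrywise to 1e-8 in the test suite.
* **Stopping.**  max|A − B| ≤ tol and max|B_t − B_{t−1}| ≤ tol with
  tol = 1e-6, max_iter = 500 by default.  At p ~ 1000 the iteration with
  the penalty parameter tied to λ does not reach this tolerance in any
  reasonable budget and instead orbits the fixed point; two safeguards
  address this honestly:
  * an unconverged run returns the ergodic (tail-averaged over the second
    half) iterate — the averaged ADMM iterate converges even when the
    last iterate oscillates — and flags `tail_averaged`; the raw final
    iterate is kept for warm starts;
  * a fit whose thresholded basis keeps no more rows than dimensions
    (a collapsed transient) is continued once from the raw final iterate
    (`extended_run` flag).
* **Over-penalized shortcut.**  While B has never left zero the iteration
  is fully predictable (C accumulates A); the dual's sup-norm growth is
  extrapolated, and the run exits early (flagged) if it cannot reach the
  soft-threshold level within the budget.  The model then returns the
  intercept-only fallback.
* **Fast-forward initialization.**  From B = C = 0 the first ~p/d
  iterations of a productive run are exactly that predictable prefix; the
  tuning path therefore starts the coldest fit from C₀ = A₀/max|A₀|
  (one projection), which has the same fixed points.  `fps_admm` itself
  defaults to the plain zero initialization.

## Penalty selection

The entrywise penalty competes with the sampling noise of off-diagonal
correlations, whose extreme magnitude is of order sqrt(log(p)/n).  The
default grid starts there and descends log-linearly over a factor of 6
(5 values): below roughly a sixth of that scale the Fantope solution
loses row sparsity entirely (hundreds of rows with tiny energies — the
degenerate entrywise regime), so smaller penalties are excluded by
default.  λ is selected on a held-out validation set by MSE (deviance for
the binomial family) with the one-standard-error rule: the largest λ
within one SE of the minimizing score.  Neighbouring penalties routinely
differ in validation MSE by far less than that score's own sampling
noise, and in that regime the sparser model is the better bet; plain
minimization (`selection="min"`, ties to the larger λ) is available.
`theoretical_lambda` exposes the λ₁·sqrt(log(p)/n) scaling as a
grid-centering helper only.

## Synthetic data

The generator reproduces the factor model above with
Λ_d = diag(d, …, 1), loadings built from an orthogonalized d×d Gaussian
block whose rows are each repeated r times (columns rescaled by 1/√r so
V_dᵀV_d = I_d survives the repetition), s = r·d true features, and noise
calibrated to prescribed signal-to-noise ratios:
σ_x² = tr(Λ_d²)/(p·SNR_x²) and
σ_y² = (β*ᵀV_dΛ_d²V_dᵀβ* + σ_x²‖β*‖²)/(n·SNR_y²).  The last component of
Θ is solved so that Φ vanishes exactly on the final group of r features:
those carry conditional signal invisible to marginal screening.  Defaults
(n = 100, p = 1000, d = 3, r = 5, SNR = 5) give 15 signal features of
which only 10 are marginally visible.

What the generator does *not* emulate about real transcriptomic data:
heavy-tailed and count-valued expression, batch effects, correlated noise
across genes beyond the factor structure, censoring in survival
phenotypes, and any mismatch between the working dimension d and the
truth.  Passing tests therefore demonstrate correctness of the machinery
and behavior under the model's own assumptions, not robustness to their
violation.

`semi_synthetic` applies the same construction on top of an empirical
basis: the leading d eigenvectors of a supplied matrix's sample
covariance, all but the largest-norm rows zeroed and re-orthonormalized,
factor scales set to the square roots of the top empirical eigenvalues.
Θ is drawn fully at random there — the zero-correlation construction
needs the repeated-row group structure, which an empirical basis lacks.

`generate_learning_curve` draws one population and nested training sets
plus a shared disjoint test set (common random numbers across sizes); by
default the response noise is recalibrated at each size so the
signal-to-noise ratio, not the noise variance, is held at its design
value — the same convention the single-size generator uses.

## Evaluation harness

SPC is implemented as absolute-Pearson-correlation screening (size tuned
on validation), PCA on the survivors, OLS on the top d components; the
oracle is OLS on the true support.  Lasso/ridge/elastic-net comparators
come from scikit-learn inside `run_experiment` and are never
re-implemented.  Feature-selection ROC curves sweep the λ grid (SuffPCR)
or the screening size (SPC); AUC is trapezoidal with the (0,0) and (1,1)
endpoints appended.  Precision of an empty selection is 1 (vacuously no
false positives).

## Problem sizes in the shipped tests

The end-to-end suite runs the favorable-conditions design (n = 100,
p = 1000, d = 3, r = 5, SNR = 5) with 5 tuned replications for the
recovery/comparison checks (ADMM budget 150 iterations per fit) and
6 seeds × nested n ∈ {100, 200, 400} for the learning-curve check
(200 iterations, since the comparison across sizes is sensitive to the
accuracy of the averaged basis).  Support and prediction stabilize well
before the strict primal tolerance; fits carry their non-convergence
flags.  Larger replication
counts reproduce the same medians; a 10-seed tuned run gave exact support
recovery (symmetric difference 0) in 10 of 10 seeds with median
test-MSE/oracle-MSE ratio 0.93.

## Known limitations

* d must be supplied; no automatic dimension selection.
* The ADMM rarely meets the strict fixed-point tolerance at p ≳ 1000;
  results rest on the averaged iterate (flagged), which is standard for
  ergodic ADMM but means reported `primal_gap` values are diagnostic, not
  certificates.
* The elbow rule's threshold equals a profile value, so one boundary row
  can survive when the iterate is only entrywise sparse; validation-based
  penalty selection usually lands in the row-sparse regime where the rule
  is exact.
* Missing values are rejected, not imputed; survival phenotypes are
  handled only via the opt-in log(Y+1) transform, not a censoring-aware
  likelihood.
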