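# suffpcr

Sufficient principal component regression (SuffPCR) for high-dimensional
transcriptomic prediction and gene selection.

## The problem

Microarray and RNA-Seq studies routinely measure thousands of transcripts
on tens to hundreds of patients, and one wants a *small* set of genes whose
expression predicts a phenotype (survival time, disease status).  The
popular screen-then-regress recipe — supervised principal components (SPC):
keep the genes most marginally correlated with the phenotype, then run PCR
on the survivors — silently requires that marginal correlation and
conditional effect agree:

```
Φ_j = 0   ⇒   β*_j = (Σ⁻¹Φ)_j = 0
```

where Σ = Cov(x), Φ = Cov(x, y) and β* is the population regression
coefficient.  Whenever a gene matters only *jointly* with others, this
fails and screening discards true signal.  A sufficient (rather than
assumed) condition comes from the eigenstructure: if row *j* of the leading
eigenvectors of Σ is zero, then β*_j = 0.  Row-sparse eigenvectors imply
sparse coefficients.

## The method

SuffPCR estimates a row-sparse d-dimensional principal subspace and then
regresses on it:

1. **Standardize** X (and center y) so S = (1/n)XᵀX is the correlation
   matrix.
2. **Sparse PCA via the Fantope relaxation.**  Solve

   ```
   max_P  tr(S P) − λ‖P‖₁,₁   subject to  P ∈ F^d
   ```

   where F^d = {P = Pᵀ : 0 ⪯ P ⪯ I, tr P = d} is the Fantope, by ADMM:
   a Euclidean projection onto F^d (computed from a *truncated*
   eigendecomposition — only the eigenpairs that survive the clip
   `min(max(eig − τ, 0), 1)` are ever needed), an elementwise
   soft-threshold, and a dual update.
3. **Automatic row thresholding.**  Take the top-d eigenvectors V_d of the
   sparse iterate, compute per-gene energies l = diag(V_d V_dᵀ), and find
   the elbow separating signal rows from the noise floor by maximizing the
   jump in the observation-weighted variance split; rows below the elbow
   are zeroed.
4. **Regress** y on the derived components X V̂_d (OLS, or unpenalized
   logistic regression for binary labels) and map back:
   **β̂ = V̂_d γ̂** — supported on the selected genes only.

λ is chosen on a held-out validation set over a log-linear grid
(one-standard-error rule).

## Worked example

```python
import numpy as np
from suffpcr import SuffPCR, FactorModelParams, generate_splits, default_lambda_grid, tune_lambda

# a draw from the row-sparse factor model: 15 true genes out of 1000,
# 5 of which have exactly zero marginal correlation with the phenotype
train, val, test = generate_splits(FactorModelParams(n=100, p=1000, d=3, r=5, seed=1))

X = np.vstack([train.X, val.X]); y = np.concatenate([train.y, val.y])
grid = default_lambda_grid(100, 1000)          # [0.2628 ... 0.0438]
best_lam, path = tune_lambda(X, y, d=3, lam_grid=grid,
                             train_idx=np.arange(100),
                             val_idx=np.arange(100, 200), max_iter=150)
res = next(r for lam, r, _ in path if lam == best_lam)
print(res.summary())
print("test MSE:", np.mean((res.predict(test.X) - test.y) ** 2))
print("true support recovered:",
      set(res.support.tolist()) == set(train.support.tolist()))
```

Output (seed 1):

```
SuffPCR results
==============================================
family              gaussian
n / p               100 / 1000
subspace dim d      3
penalty lambda      0.262826
row threshold t     0
features selected   15
ADMM iterations     150 (primal gap 1.02e-02)
flags               admm_not_converged, tail_averaged
----------------------------------------------
top 10 features by |beta|:
  feature_3                 1.585586
  feature_2                 1.582516
  feature_4                 1.576625
  feature_1                 1.572833
  feature_0                 1.566940
  feature_7                -1.419066
  feature_8                -1.416901
  feature_5                -1.412363
  feature_6                -1.407636
  feature_9                -1.403012
test MSE: 0.03177095618305846
true support recovered: True
```

The model selects exactly the 15 planted genes — including the 5 that
marginal screening can never see — and predicts at the accuracy of the
oracle that is told the true genes (test MSE 0.032 vs oracle 0.030 on this
draw).

A command-line interface covers the same workflow on delimited files:

```bash
suffpcr simulate --n 100 --p 1000 --d 3 --r 5 --seed 1 --out-prefix sim
suffpcr fit --expression sim_expression.csv --phenotype sim_phenotype.csv \
            --d 3 --seed 1 --out fit.json --genes genes.txt
suffpcr predict --fit fit.json --expression sim_expression.csv --out pred.csv
suffpcr evaluate --config experiment.yaml --out results.csv
```

`evaluate` writes a tidy table with one row per replication × method and
columns `replication, method, mse, n_selected, precision, recall`.

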