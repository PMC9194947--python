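"""Metrics, baselines and the replication harness for simulation studies.

Baselines implemented here:

* SPC (supervised principal components): screen features by absolute
  marginal correlation with the phenotype, PCA on the survivors,
  regress on the top components.  It fails by construction on features
  whose marginal correlation is zero but whose conditional effect is
  not.
* Oracle OLS: least squares restricted to the true support — the
  information-unavailable reference.

Lasso / ridge / elastic net comparators are delegated to scikit-learn
inside :func:`run_experiment` and never re-implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    SuffPCR,
    apply_standardization,
    default_lambda_grid,
    standardize,
    tune_lambda,
)
from .simulate import FactorModelParams, SyntheticDataset, generate_splits

__all__ = [
    "SelectionMetrics",
    "RocPath",
    "prediction_mse",
    "selection_metrics",
    "roc_path",
    "spc_baseline",
    "oracle_ols",
    "run_experiment",
    "EXPERIMENT_COLUMNS",
]

EXPERIMENT_COLUMNS = [
    "replication", "method", "mse", "n_selected", "precision", "recall",
]


@dataclass
class SelectionMetrics:
    n_selected: int
    precision: float
    recall: float


@dataclass
class RocPath:
    """(FPR, TPR) points swept over a tuning parameter, plus the
    trapezoidal area under the curve (computed with the (0,0) and (1,1)
    endpoints appended)."""

    points: list
    auc: float


def prediction_mse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    return float(np.mean((y_true - y_pred) ** 2))


def selection_metrics(est_support, true_support, p: int) -> SelectionMetrics:
    """Precision/recall of a selected feature set against the truth.

    An empty selection has precision 1 (vacuously, no false positives);
    an empty truth has recall 1 only when nothing was selected.
    """
    est = set(int(j) for j in np.atleast_1d(np.asarray(est_support, dtype=int)))
    true = set(int(j) for j in np.atleast_1d(np.asarray(true_support, dtype=int)))
    if any(j < 0 or j >= p for j in est | true):
        raise ValueError("support indices outside [0, p)")
    tp = len(est & true)
    precision = tp / len(est) if est else 1.0
    if true:
        recall = tp / len(true)
    else:
        recall = 1.0 if not est else 0.0
    return SelectionMetrics(n_selected=len(est), precision=precision,
                            recall=recall)


def _auc(points: list) -> float:
    pts = sorted(set(points) | {(0.0, 0.0), (1.0, 1.0)})
    fpr = np.array([q[0] for q in pts])
    tpr = np.array([q[1] for q in pts])
    return float(np.trapezoid(tpr, fpr))


def roc_path(method, data, grid, d: int | None = None) -> RocPath:
    """Feature-selection ROC swept over a tuning parameter.

    ``method`` is ``"suffpcr"`` (grid of penalties ``lam``, descending
    with warm starts, elbow threshold applied per fit) or ``"spc"``
    (grid of screening sizes ``n_keep``), or any callable
    ``grid_value -> support``.  ``data`` is a :class:`SyntheticDataset`
    (its ``support`` is the truth).  Degenerate truth (no true features,
    or all features true) is rejected.
    """
    if len(list(grid)) == 0:
        raise ValueError("empty grid")
    true = set(int(j) for j in data.support)
    p = data.p
    if not true or len(true) == p:
        raise ValueError("degenerate truth: ROC undefined")

    supports = []
    if callable(method):
        supports = [np.atleast_1d(method(g)) for g in grid]
    elif method == "suffpcr":
        dd = d if d is not None else data.params.d
        m = SuffPCR(data.y, data.X, d=dd, family="gaussian")
        init = None
        for lam in sorted(grid, reverse=True):
            res = m.fit(lam, keep_admm=True, admm_init=init)
            init = (res.admm_B, res.admm_C)
            supports.append(res.support)
    elif method == "spc":
        dd = d if d is not None else data.params.d
        for n_keep in grid:
            supports.append(
                spc_baseline(data.X, data.y, dd, int(n_keep)).support
            )
    else:
        raise ValueError(f"unknown method {method!r}")

    points = []
    n_true = len(true)
    n_false = p - n_true
    for sup in supports:
        est = set(int(j) for j in sup)
        tp = len(est & true)
        fp = len(est - true)
        points.append((fp / n_false, tp / n_true))
    points.sort()
    return RocPath(points=points, auc=_auc(points))


@dataclass
class BaselineFit:
    """SPC / oracle fit with the same prediction surface as a SuffPCR
    results object (beta on the standardized scale plus an intercept)."""

    beta_std: np.ndarray
    intercept: float
    support: np.ndarray
    std_params: object

    @property
    def n_selected(self) -> int:
        return int(self.support.size)

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        Xs = apply_standardization(self.std_params, np.asarray(Xnew, float))
        return Xs @ self.beta_std + self.intercept

    @property
    def params(self) -> np.ndarray:
        beta = np.zeros(self.std_params.p_original)
        beta[self.std_params.kept] = self.beta_std
        return beta


def spc_baseline(X: np.ndarray, y: np.ndarray, d: int, n_keep: int) -> BaselineFit:
    """Supervised principal components: keep the ``n_keep`` features with
    the largest absolute marginal correlation with ``y``, run PCA on the
    kept block, OLS of ``y`` on the top ``d`` components, and embed the
    coefficients back into all ``p`` features (zeros off the kept set)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not d <= n_keep <= p:
        raise ValueError(f"need d <= n_keep <= p, got n_keep={n_keep}")
    Xs, ys, std = standardize(X, y, family="gaussian")
    cor = np.abs(Xs.T @ ys) / n / max(float(np.std(ys)), 1e-300)
    n_keep_eff = min(n_keep, Xs.shape[1])
    kept = np.sort(np.argsort(-cor, kind="stable")[:n_keep_eff])
    block = Xs[:, kept]
    # PCA on the screened block: top-d right singular vectors
    _, _, Vt = np.linalg.svd(block, full_matrices=False)
    W = Vt[:d].T
    scores = block @ W
    gamma, *_ = np.linalg.lstsq(scores, ys, rcond=None)
    beta_std = np.zeros(Xs.shape[1])
    beta_std[kept] = W @ gamma
    return BaselineFit(
        beta_std=beta_std,
        intercept=std.response_center,
        support=std.kept[kept],
        std_params=std,
    )


def oracle_ols(X: np.ndarray, y: np.ndarray, true_support) -> BaselineFit:
    """OLS restricted to the true features (centered/scaled like the
    other methods); rejects singular restricted designs."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    support = np.sort(np.asarray(true_support, dtype=int))
    if support.size >= X.shape[0]:
        raise ValueError("|true_support| must be smaller than n")
    Xs, ys, std = standardize(X, y, family="gaussian")
    pos = np.searchsorted(std.kept, support)
    if not np.array_equal(std.kept[pos], support):
        raise ValueError("true support includes a zero-variance feature")
    block = Xs[:, pos]
    beta_sub, _, rank, _ = np.linalg.lstsq(block, ys, rcond=None)
    if rank < support.size:
        raise ValueError("singular design on the true support")
    beta_std = np.zeros(Xs.shape[1])
    beta_std[pos] = beta_sub
    return BaselineFit(
        beta_std=beta_std,
        intercept=std.response_center,
        support=support,
        std_params=std,
    )


def _sklearn_linear(name: str, Xtr, ytr, Xval, yval, seed: int):
    """Tune a packaged linear baseline on the validation split; returns
    (predict_fn, support)."""
    from sklearn.linear_model import ElasticNet, Lasso, Ridge

    alphas = np.geomspace(1e-3, 10.0, 10)
    best = (np.inf, None)
    for a in alphas:
        if name == "lasso":
            est = Lasso(alpha=a, max_iter=5000)
        elif name == "ridge":
            est = Ridge(alpha=a)
        elif name == "elasticnet":
            est = ElasticNet(alpha=a, l1_ratio=0.5, max_iter=5000)
        else:
            raise ValueError(name)
        est.fit(Xtr, ytr)
        score = prediction_mse(yval, est.predict(Xval))
        if score < best[0]:
            best = (score, est)
    est = best[1]
    support = np.flatnonzero(np.abs(np.ravel(est.coef_)) > 0)
    if name == "ridge":
        support = np.arange(Xtr.shape[1])
    return est.predict, support


def _default_config() -> dict:
    return {
        "n": 100, "p": 1000, "d": 3, "r": 5,
        "snr_x": 5.0, "snr_y": 5.0,
        "n_replications": 50,
        "seed": 0,
        "methods": ["suffpcr", "spc", "oracle"],
        "lambda_grid_size": 5,
        "lambda_grid_span": 6.0,
        "n_keep_grid": None,  # default derived from s below
        "admm_tol": 1e-6,
        "admm_max_iter": 150,
    }


def run_experiment(config: dict | None = None) -> pd.DataFrame:
    """Seeded replication loop over synthetic draws.

    Each replication draws train/validation/test sets from one
    population, tunes every method on validation MSE only, and records
    test MSE plus selection metrics.  A method failure in one
    replication is recorded as missing and the loop continues.  Returns
    a tidy table, one row per replication x method.
    """
    cfg = _default_config()
    if config:
        cfg.update(config)
    params0 = FactorModelParams(
        n=cfg["n"], p=cfg["p"], d=cfg["d"], r=cfg["r"],
        snr_x=cfg["snr_x"], snr_y=cfg["snr_y"], seed=cfg["seed"],
    )
    s = params0.s
    n_keep_grid = cfg["n_keep_grid"] or [s, 2 * s, 4 * s, 8 * s]
    n_keep_grid = [k for k in n_keep_grid if cfg["d"] <= k <= cfg["p"]]
    ss = np.random.SeedSequence(cfg["seed"])
    rep_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in
                 ss.spawn(cfg["n_replications"])]

    rows = []
    for rep, rseed in enumerate(rep_seeds):
        params = FactorModelParams(
            n=cfg["n"], p=cfg["p"], d=cfg["d"], r=cfg["r"],
            snr_x=cfg["snr_x"], snr_y=cfg["snr_y"], seed=rseed,
        )
        train, val, test = generate_splits(params)
        true_support = train.support
        n = params.n
        Xfit = np.vstack([train.X, val.X])
        yfit = np.concatenate([train.y, val.y])
        tr_idx = np.arange(n)
        va_idx = np.arange(n, 2 * n)

        for method in cfg["methods"]:
            try:
                if method == "suffpcr":
                    grid = default_lambda_grid(
                        n, cfg["p"], num=cfg["lambda_grid_size"],
                        span=cfg["lambda_grid_span"],
                    )
                    best_lam, path = tune_lambda(
                        Xfit, yfit, cfg["d"], grid, tr_idx, va_idx,
                        tol=cfg["admm_tol"], max_iter=cfg["admm_max_iter"],
                    )
                    res = next(r for lam, r, _ in path if lam == best_lam)
                    pred = res.predict(test.X)
                    sup = res.support
                elif method == "spc":
                    best = (np.inf, None)
                    for k in n_keep_grid:
                        f = spc_baseline(train.X, train.y, cfg["d"], k)
                        sc = prediction_mse(val.y, f.predict(val.X))
                        if sc < best[0]:
                            best = (sc, f)
                    f = best[1]
                    pred = f.predict(test.X)
                    sup = f.support
                elif method == "oracle":
                    f = oracle_ols(train.X, train.y, true_support)
                    pred = f.predict(test.X)
                    sup = f.support
                elif method in ("lasso", "ridge", "elasticnet"):
                    predict_fn, sup = _sklearn_linear(
                        method, train.X, train.y, val.X, val.y, rseed
                    )
                    pred = predict_fn(test.X)
                else:
                    raise ValueError(f"unknown method {method!r}")
                mse = prediction_mse(test.y, pred)
                sel = selection_metrics(sup, true_support, cfg["p"])
                rows.append([rep, method, mse, sel.n_selected,
                             sel.precision, sel.recall])
            except Exception:  # noqa: BLE001 - record failure, keep looping
                rows.append([rep, method, np.nan, np.nan, np.nan, np.nan])
    return pd.DataFrame(rows, columns=EXPERIMENT_COLUMNS)
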