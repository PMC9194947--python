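"""Sufficient principal component regression (SuffPCR).

The estimator, end to end: standardize X (and center y) so the sample
second-moment matrix ``S = (1/n) Xs^T Xs`` is the correlation matrix;
run the Fantope ADMM on ``S`` with penalty ``lam``; take the top-``d``
eigenvectors of the sparse iterate ``B``; hard-threshold rows by the
automatic elbow rule; regress the response on the derived components
``Xs V_hat`` (ordinary least squares, or an unpenalized logistic model
for binary labels); and map the low-dimensional coefficients back as
``beta_hat = V_hat gamma_hat``.  Because ``V_hat`` is row sparse,
``beta_hat`` is supported on the same small feature set.

Two surfaces are provided: a statsmodels-style :class:`SuffPCR` model
object whose :meth:`SuffPCR.fit` returns a :class:`SuffPCRResults`, and
thin module-level functions (:func:`fit`, :func:`fit_logistic`,
:func:`predict`, :func:`tune_lambda`) over the same code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.linalg import ArpackError, ArpackNoConvergence, eigsh

from .fantope import ADMMState, fps_admm
from .threshold import (
    EmptySupportError,
    RowEnergyProfile,
    SparseSubspace,
    apply_row_threshold,
    elbow_threshold,
)

__all__ = [
    "StandardizationParams",
    "SuffPCR",
    "SuffPCRResults",
    "standardize",
    "apply_standardization",
    "fit",
    "fit_logistic",
    "predict",
    "tune_lambda",
    "theoretical_lambda",
    "default_lambda_grid",
]


@dataclass
class StandardizationParams:
    """Column centering/scaling learned on the training data.

    ``kept`` indexes the retained (positive-variance) columns of the
    original feature set; ``dropped`` the zero-variance columns removed
    before fitting.  Scales are population (1/n) standard deviations so
    that ``(1/n) Xs^T Xs`` has unit diagonal.
    """

    feature_means: np.ndarray
    feature_scales: np.ndarray
    kept: np.ndarray
    dropped: np.ndarray
    response_center: float = 0.0
    p_original: int = 0


def standardize(
    X: np.ndarray, y: np.ndarray | None = None, family: str = "gaussian"
) -> tuple[np.ndarray, np.ndarray | None, StandardizationParams]:
    """Center/scale columns of X to mean 0, (1/n)-variance 1; center y
    (Gaussian family only).  Zero-variance columns are dropped with a
    warning and reported by index — never silently scaled by zero."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two observations")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; imputation is not supported")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    kept = np.flatnonzero(scales > 0.0)
    dropped = np.flatnonzero(scales == 0.0)
    if dropped.size:
        warnings.warn(
            f"dropping {dropped.size} zero-variance feature(s): "
            f"{dropped.tolist()[:10]}{'...' if dropped.size > 10 else ''}",
            RuntimeWarning,
            stacklevel=2,
        )
    Xs = (X[:, kept] - means[kept]) / scales[kept]
    ys = None
    center = 0.0
    if y is not None:
        y = np.asarray(y, dtype=float).ravel()
        if y.size != n:
            raise ValueError("y length does not match X")
        if np.isnan(y).any():
            raise ValueError("y contains missing values")
        if family == "gaussian":
            center = float(y.mean())
            ys = y - center
        else:
            ys = y.copy()
    params = StandardizationParams(
        feature_means=means[kept],
        feature_scales=scales[kept],
        kept=kept,
        dropped=dropped,
        response_center=center,
        p_original=p,
    )
    return Xs, ys, params


def apply_standardization(
    params: StandardizationParams, Xnew: np.ndarray
) -> np.ndarray:
    """Apply stored training centering/scaling to new data (retained
    columns only)."""
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.ndim == 1:
        Xnew = Xnew[None, :]
    if Xnew.shape[1] != params.p_original:
        raise ValueError(
            f"expected {params.p_original} features, got {Xnew.shape[1]}"
        )
    if np.isnan(Xnew).any():
        raise ValueError("new data contain missing values")
    return (Xnew[:, params.kept] - params.feature_means) / params.feature_scales


def theoretical_lambda(S: np.ndarray, n: int) -> float:
    """Theory-guided penalty scale ``lambda_1(S) * sqrt(log(p) / n)``;
    used only to center the default tuning grid."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    try:
        lam1 = float(eigsh(S, k=1, which="LA", return_eigenvectors=False)[0])
    except (ArpackError, ArpackNoConvergence):  # pragma: no cover
        lam1 = float(np.linalg.eigvalsh(S)[-1])
    return lam1 * float(np.sqrt(np.log(p) / n))


def default_lambda_grid(
    n: int, p: int, num: int = 5, span: float = 6.0, scale: float = 1.0
) -> np.ndarray:
    """Log-linearly spaced penalty grid (descending).

    On the correlation scale of ``S``, the entrywise penalty competes
    with sampling noise in the off-diagonal correlations, whose extreme
    magnitude is of order ``sqrt(log(p)/n)``.  The grid therefore starts
    at ``scale * sqrt(log(p)/n)`` and descends log-linearly over a
    factor of ``span``; validation selects within it.
    """
    top = scale * float(np.sqrt(np.log(p) / n))
    return np.geomspace(top, top / span, num)


def _top_d_eigvecs(B: np.ndarray, d: int) -> np.ndarray:
    """Top-d eigenvectors of a symmetric matrix, by algebraic eigenvalue,
    with a deterministic sign convention (largest-magnitude entry > 0)."""
    p = B.shape[0]
    if p <= 400 or d >= p - 1:
        w, V = eigh(B)
        V = V[:, ::-1][:, :d]
    else:
        v0 = np.full(p, 1.0 / np.sqrt(p))
        try:
            w, V = eigsh(B, k=d, which="LA", v0=v0)
            V = V[:, np.argsort(w)[::-1]]
        except (ArpackError, ArpackNoConvergence):
            w, V = eigh(B)
            V = V[:, ::-1][:, :d]
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


class SuffPCR:
    """SuffPCR model: row-sparse PCA on the feature correlation matrix,
    then regression on the recovered components.

    Parameters
    ----------
    endog : (n,) array
        Phenotype: continuous for ``family="gaussian"``, {0, 1} labels
        for ``family="binomial"``.
    exog : (n, p) array
        Expression matrix, rows = samples, columns = features.
    d : int
        Target subspace dimension (a user input; there is no automatic
        selection).
    family : {"gaussian", "binomial"}
    feature_names : sequence of str, optional
        Feature identifiers used in summaries, gene lists and
        serialization.
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        d: int = 3,
        family: str = "gaussian",
        feature_names=None,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2:
            raise ValueError("exog must be 2-D")
        n, p = self.exog.shape
        if self.endog.size != n:
            raise ValueError("endog and exog have different numbers of samples")
        if family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {family!r}")
        if family == "binomial":
            classes = np.unique(self.endog)
            if not np.all(np.isin(classes, (0.0, 1.0))):
                raise ValueError("binomial family needs labels in {0, 1}")
            if classes.size < 2:
                raise ValueError("both classes must be present")
        if not 1 <= d < min(n, p):
            raise ValueError(f"need 1 <= d < min(n, p) = {min(n, p)}, got d={d}")
        self.d = int(d)
        self.family = family
        self.feature_names = (
            None if feature_names is None else [str(f) for f in feature_names]
        )
        if self.feature_names is not None and len(self.feature_names) != p:
            raise ValueError("feature_names length does not match exog")
        self.n, self.p = n, p
        self._Xs = None
        self._ys = None
        self._std = None
        self._S = None

    @classmethod
    def from_dataframe(cls, data, phenotype, d=3, family="gaussian"):
        """Build from a samples-by-features DataFrame and the name of the
        phenotype column (or a separate Series aligned on the index)."""
        import pandas as pd

        if isinstance(phenotype, str):
            y = data[phenotype].to_numpy()
            X = data.drop(columns=[phenotype])
        else:
            y = pd.Series(phenotype).reindex(data.index).to_numpy()
            if np.isnan(y).any():
                raise ValueError("phenotype index does not cover all samples")
            X = data
        return cls(
            y, X.to_numpy(dtype=float), d=d, family=family,
            feature_names=list(X.columns),
        )

    # -- internal, computed once and reused across a lambda path --------
    def _prepare(self) -> None:
        if self._S is None:
            self._Xs, self._ys, self._std = standardize(
                self.exog, self.endog, family=self.family
            )
            self._S = self._Xs.T @ self._Xs / self.n

    @property
    def S(self) -> np.ndarray:
        """Sample correlation matrix of the retained features."""
        self._prepare()
        return self._S

    def fit(
        self,
        lam: float,
        tol: float = 1e-6,
        max_iter: int = 500,
        admm_init: tuple[np.ndarray, np.ndarray] | None = None,
        keep_admm: bool = False,
        logit_max_iter: int = 200,
        init: str = "zero",
    ) -> "SuffPCRResults":
        """Fit at a single penalty value ``lam > 0``.

        ``admm_init`` may carry ``(B, C)`` from a previous (larger)
        ``lam`` to warm start the ADMM.  With ``keep_admm=True`` the
        final ``(B, C)`` are kept on the results for further warm
        starts.
        """
        self._prepare()
        if lam <= 0:
            raise ValueError("lam must be positive")
        B0, C0 = admm_init if admm_init is not None else (None, None)
        B, state = fps_admm(
            self._S, self.d, lam, tol=tol, max_iter=max_iter, B0=B0, C0=C0,
            init=init, tail_average=True,
        )
        extended = False
        if not state.converged and not state.zero_stalled and B.any():
            # a degenerate basis (no more rows than dimensions) from an
            # unconverged run usually means the iterate was caught in a
            # transient; continue from the raw last iterate once
            probe = _top_d_eigvecs(B, self.d)
            t_probe, _ = elbow_threshold(RowEnergyProfile.from_basis(probe))
            try:
                n_rows = apply_row_threshold(probe, t_probe).support.size
            except EmptySupportError:
                n_rows = 0
            if n_rows <= self.d:
                B, state = fps_admm(
                    self._S, self.d, lam, tol=tol, max_iter=max_iter,
                    B0=state.B_last, C0=state.C, tail_average=True,
                )
                extended = True
        flags: list[str] = []
        if extended:
            flags.append("extended_run")
        if state.zero_stalled:
            flags.append("over_penalized")
        elif not state.converged:
            flags.append("admm_not_converged")
        if state.tail_averaged:
            flags.append("tail_averaged")

        if not np.any(B):
            flags.append("empty_support")
            res = self._intercept_only(lam, state, flags)
        else:
            V_d = _top_d_eigvecs(B, self.d)
            profile = RowEnergyProfile.from_basis(V_d)
            t, _ = elbow_threshold(profile)
            try:
                subspace = apply_row_threshold(V_d, t)
            except EmptySupportError:
                flags.append("empty_support")
                res = self._intercept_only(lam, state, flags, t=t)
            else:
                res = self._regress(subspace, lam, t, state, flags,
                                    logit_max_iter)
        if keep_admm:
            # warm starts continue from the raw final iterate, not the
            # tail average
            res.admm_B, res.admm_C = state.B_last, state.C
        return res

    def _intercept_only(self, lam, state, flags, t=0.0) -> "SuffPCRResults":
        std = self._std
        if self.family == "gaussian":
            intercept = std.response_center
        else:
            pbar = float(np.clip(self.endog.mean(), 1e-12, 1 - 1e-12))
            intercept = float(np.log(pbar / (1 - pbar)))
        subspace = SparseSubspace(
            V=np.zeros((std.kept.size, self.d)),
            support=np.array([], dtype=int),
            threshold=float(t),
        )
        return SuffPCRResults(
            model=self,
            V_hat=subspace,
            gamma=np.zeros(self.d),
            beta_std=np.zeros(std.kept.size),
            intercept=intercept,
            lam=float(lam),
            t=float(t),
            admm_state=state,
            flags=flags,
        )

    def _regress(
        self, subspace: SparseSubspace, lam, t, state, flags, logit_max_iter
    ) -> "SuffPCRResults":
        Z = self._Xs @ subspace.V  # n x d derived components
        if self.family == "gaussian":
            gamma, *_ = np.linalg.lstsq(Z, self._ys, rcond=None)
            intercept = self._std.response_center
        else:
            from sklearn.exceptions import ConvergenceWarning
            from sklearn.linear_model import LogisticRegression

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=ConvergenceWarning)
                lr = LogisticRegression(
                    penalty=None, solver="lbfgs", max_iter=logit_max_iter
                )
                lr.fit(Z, self._ys)
            gamma = lr.coef_.ravel()
            intercept = float(lr.intercept_[0])
            scores = Z @ gamma + intercept
            perfect = np.all((scores > 0) == (self._ys > 0.5))
            if perfect and np.abs(gamma).max() > 10.0:
                flags = flags + ["separation"]
        beta_std = subspace.V @ gamma
        return SuffPCRResults(
            model=self,
            V_hat=subspace,
            gamma=np.asarray(gamma, dtype=float),
            beta_std=beta_std,
            intercept=float(intercept),
            lam=float(lam),
            t=float(t),
            admm_state=state,
            flags=flags,
        )


@dataclass
class SuffPCRResults:
    """A fitted SuffPCR model.

    ``beta_std`` lives on the standardized-feature scale over the
    retained columns; :attr:`params` maps it back to the full original
    feature set (zeros at dropped and non-support positions), and
    :attr:`beta_original`/:attr:`intercept_original` give the
    original-units linear predictor.
    """

    model: SuffPCR
    V_hat: SparseSubspace
    gamma: np.ndarray
    beta_std: np.ndarray
    intercept: float
    lam: float
    t: float
    admm_state: ADMMState
    flags: list = field(default_factory=list)
    admm_B: np.ndarray | None = field(default=None, repr=False)
    admm_C: np.ndarray | None = field(default=None, repr=False)

    # -- coefficient views ----------------------------------------------
    @property
    def params(self) -> np.ndarray:
        """beta_hat = V_hat gamma_hat scattered into original feature
        order (standardized scale)."""
        std = self.model._std
        beta = np.zeros(std.p_original)
        beta[std.kept] = self.beta_std
        return beta

    @property
    def support(self) -> np.ndarray:
        """Original indices of the selected features."""
        return self.model._std.kept[self.V_hat.support]

    @property
    def support_names(self) -> list:
        names = self.model.feature_names
        if names is None:
            return [int(j) for j in self.support]
        return [names[j] for j in self.support]

    @property
    def n_selected(self) -> int:
        return int(self.V_hat.support.size)

    @property
    def converged(self) -> bool:
        return "admm_not_converged" not in self.flags

    @property
    def beta_original(self) -> np.ndarray:
        """Coefficients on the original (unstandardized) feature scale."""
        std = self.model._std
        beta = np.zeros(std.p_original)
        beta[std.kept] = self.beta_std / std.feature_scales
        return beta

    @property
    def intercept_original(self) -> float:
        std = self.model._std
        shift = float(np.dot(self.beta_std / std.feature_scales,
                             std.feature_means))
        return self.intercept - shift

    # -- prediction ------------------------------------------------------
    def _resolve_features(self, Xnew) -> np.ndarray:
        names = self.model.feature_names
        try:
            import pandas as pd

            if isinstance(Xnew, pd.DataFrame):
                if names is None:
                    return Xnew.to_numpy(dtype=float)
                missing = [f for f in names if f not in Xnew.columns]
                if missing:
                    raise ValueError(
                        f"new data are missing {len(missing)} training "
                        f"feature(s): {missing[:10]}"
                    )
                return Xnew.loc[:, names].to_numpy(dtype=float)
        except ImportError:  # pragma: no cover
            pass
        X = np.asarray(Xnew, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.model.p:
            raise ValueError(
                f"expected {self.model.p} features, got {X.shape[1]}"
            )
        return X

    def predict(self, Xnew) -> np.ndarray:
        """Predicted phenotype (Gaussian) or class-1 probability
        (binomial).  ``Xnew`` must carry the full training feature set;
        only support features influence the output."""
        X = self._resolve_features(Xnew)
        Xs = apply_standardization(self.model._std, X)
        eta = Xs @ self.beta_std + self.intercept
        if self.model.family == "gaussian":
            return eta
        return 1.0 / (1.0 + np.exp(-eta))

    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    # -- reporting -------------------------------------------------------
    def summary(self, top: int = 10) -> str:
        m = self.model
        lines = [
            "SuffPCR results",
            "=" * 46,
            f"family              {m.family}",
            f"n / p               {m.n} / {m.p}",
            f"subspace dim d      {m.d}",
            f"penalty lambda      {self.lam:.6g}",
            f"row threshold t     {self.t:.6g}",
            f"features selected   {self.n_selected}",
            f"ADMM iterations     {self.admm_state.iterations}"
            f" (primal gap {self.admm_state.primal_gap:.2e})",
            f"flags               {', '.join(self.flags) or 'none'}",
            "-" * 46,
        ]
        beta = self.params
        order = self.support[np.argsort(-np.abs(beta[self.support]))][:top]
        names = m.feature_names
        lines.append(f"top {min(top, order.size)} features by |beta|:")
        for j in order:
            label = names[j] if names is not None else f"feature_{j}"
            lines.append(f"  {label:<24s} {beta[j]: .6f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # keep dataclass repr from dumping arrays
        return (
            f"<SuffPCRResults family={self.model.family} lam={self.lam:.4g} "
            f"selected={self.n_selected} flags={self.flags}>"
        )


# -- functional surface over the model object ---------------------------

def fit(
    X: np.ndarray,
    y: np.ndarray,
    d: int,
    lam: float,
    feature_names=None,
    **kwargs,
) -> SuffPCRResults:
    """Gaussian-family SuffPCR at a single penalty value."""
    return SuffPCR(y, X, d=d, family="gaussian",
                   feature_names=feature_names).fit(lam, **kwargs)


def fit_logistic(
    X: np.ndarray,
    labels: np.ndarray,
    d: int,
    lam: float,
    feature_names=None,
    **kwargs,
) -> SuffPCRResults:
    """Classification variant: the final regression step is an
    unpenalized logistic model of the labels on the derived components."""
    return SuffPCR(labels, X, d=d, family="binomial",
                   feature_names=feature_names).fit(lam, **kwargs)


def predict(fit_result: SuffPCRResults, Xnew) -> np.ndarray:
    return fit_result.predict(Xnew)


def _validation_score(res: SuffPCRResults, Xval, yval) -> tuple[float, float]:
    """(score, standard error of the score) on the validation set:
    MSE for the Gaussian family, total deviance for the binomial."""
    pred = res.predict(Xval)
    yval = np.asarray(yval, dtype=float).ravel()
    m = yval.size
    if res.model.family == "gaussian":
        sq = (yval - pred) ** 2
        return float(sq.mean()), float(sq.std(ddof=1) / np.sqrt(m))
    p = np.clip(pred, 1e-12, 1 - 1e-12)
    dev = -2.0 * (yval * np.log(p) + (1 - yval) * np.log(1 - p))
    return float(dev.sum()), float(dev.std(ddof=1) * np.sqrt(m))


def tune_lambda(
    X: np.ndarray,
    y: np.ndarray,
    d: int,
    lam_grid,
    train_idx,
    val_idx,
    family: str = "gaussian",
    feature_names=None,
    tol: float = 1e-6,
    max_iter: int = 500,
    init: str = "fast_forward",
    selection: str = "1se",
) -> tuple[float, list]:
    """Select the penalty on a held-out validation set.

    Fits on the training rows for every ``lam`` in the (deduplicated)
    grid — descending, warm-starting each ADMM from the previous
    solution — and scores each fit by validation MSE (Gaussian) or
    deviance (binomial).

    ``selection="min"`` picks the score minimizer (ties to the larger,
    sparser ``lam``).  The default ``"1se"`` is the usual one-standard-
    error rule: the largest ``lam`` whose score is within one standard
    error of the minimum.  Validation scores of neighbouring penalties
    routinely differ by far less than their own sampling noise, and the
    sparser model is the better bet in that regime.

    Returns ``(best_lam, path)`` where ``path`` is a list of
    ``(lam, results, score)`` in descending-``lam`` order.
    """
    lam_grid = list(dict.fromkeys(float(l) for l in np.atleast_1d(lam_grid)))
    if not lam_grid:
        raise ValueError("empty lambda grid")
    train_idx = np.asarray(train_idx, dtype=int)
    val_idx = np.asarray(val_idx, dtype=int)
    if np.intersect1d(train_idx, val_idx).size:
        raise ValueError("train and validation indices overlap")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()

    m = SuffPCR(y[train_idx], X[train_idx], d=d, family=family,
                feature_names=feature_names)
    Xval, yval = X[val_idx], y[val_idx]
    if selection not in ("min", "1se"):
        raise ValueError(f"unknown selection rule {selection!r}")
    path = []
    errors = []
    warm = None
    for lam in sorted(lam_grid, reverse=True):
        res = m.fit(lam, tol=tol, max_iter=max_iter, admm_init=warm,
                    keep_admm=True, init=init)
        warm = (res.admm_B, res.admm_C)
        score, se = _validation_score(res, Xval, yval)
        path.append((lam, res, score))
        errors.append(se)
    scores = np.array([s for _, _, s in path])
    i_min = int(np.argmin(scores))  # first = largest lam on exact ties
    if selection == "min":
        best_lam = path[i_min][0]
    else:
        cutoff = scores[i_min] + errors[i_min]
        best_lam = path[int(np.argmax(scores <= cutoff))][0]
    return best_lam, path
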