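"""Row-sparse spiked factor-model simulator and population quantities.

The generative model: latent factors ``u_i ~ N(0, I_d)``, loadings
``V_d`` (p x d, orthonormal columns, only ``s = r*d`` nonzero rows laid
out in ``d`` blocks of ``r`` repeated rows), factor scales
``Lambda_d = diag(d, d-1, ..., 1)``, and

    x_i = u_i^T Lambda_d V_d^T + sigma_x e_i,    e_i ~ N(0, I_p)
    y_i = u_i^T Theta + sigma_y z_i,             z_i ~ N(0, 1)

so ``Sigma = V L V^T`` with eigenvalues ``l_i = lambda_i^2 + sigma_x^2``
for ``i <= d`` and ``sigma_x^2`` otherwise.  Population quantities:

    Phi    = V_d Lambda_d Theta            (marginal covariance with y)
    beta*  = V_d L_d^{-1} Lambda_d Theta   (population OLS coefficient)

The last component of ``Theta`` is solved so that ``Phi`` vanishes on
the final block of ``r`` features: those features carry signal
(``beta* != 0``) that marginal-correlation screening can never see.
Noise levels are calibrated to prescribed signal-to-noise ratios:
``sigma_x^2 = tr(Lambda_d^2) / (p SNR_x^2)`` and
``sigma_y^2 = (beta*^T V_d Lambda_d^2 V_d^T beta* + sigma_x^2 ||beta*||^2)
/ (n SNR_y^2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "FactorModelParams",
    "SyntheticDataset",
    "build_loadings",
    "solve_theta_last",
    "calibrate_noise",
    "generate",
    "generate_splits",
    "screening_fnr",
    "semi_synthetic",
]

logger = logging.getLogger(__name__)


@dataclass
class FactorModelParams:
    """Inputs of the generator; defaults are the favorable-conditions
    design (n=100, p=1000, d=3, r=5, SNR_x = SNR_y = 5)."""

    n: int = 100
    p: int = 1000
    d: int = 3
    r: int = 5
    snr_x: float = 5.0
    snr_y: float = 5.0
    seed: int = 0
    lambda_diag: np.ndarray | None = None  # defaults to (d, d-1, ..., 1)

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("d must be >= 2 (Theta_d needs d-1 free components)")
        if self.r * self.d > self.p:
            raise ValueError("s = r*d must not exceed p")
        if self.snr_x <= 0 or self.snr_y <= 0:
            raise ValueError("SNRs must be positive")

    @property
    def s(self) -> int:
        return self.r * self.d

    def lambdas(self) -> np.ndarray:
        if self.lambda_diag is not None:
            return np.asarray(self.lambda_diag, dtype=float)
        return np.arange(self.d, 0, -1, dtype=float)


@dataclass
class SyntheticDataset:
    """A draw from the factor model together with its ground truth."""

    X: np.ndarray
    y: np.ndarray
    V_d: np.ndarray
    Theta: np.ndarray
    beta_star: np.ndarray
    Phi: np.ndarray
    sigma_x: float
    sigma_y: float
    support: np.ndarray
    phi_zero_group: np.ndarray
    lambda_diag: np.ndarray
    params: FactorModelParams | None = None
    U: np.ndarray = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray) -> "SyntheticDataset":
        """Same population, a subset of the observations."""
        return SyntheticDataset(
            X=self.X[rows],
            y=self.y[rows],
            V_d=self.V_d,
            Theta=self.Theta,
            beta_star=self.beta_star,
            Phi=self.Phi,
            sigma_x=self.sigma_x,
            sigma_y=self.sigma_y,
            support=self.support,
            phi_zero_group=self.phi_zero_group,
            lambda_diag=self.lambda_diag,
            params=self.params,
            U=None if self.U is None else self.U[rows],
        )


def build_loadings(
    p: int, d: int, r: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the row-sparse orthonormal loading matrix ``V_d``.

    A d x d standard-normal matrix is orthogonalized (QR), each row is
    repeated ``r`` times to form the s x d top block (s = r*d), the
    remaining p - s rows are zero, and columns are rescaled by 1/sqrt(r)
    so ``V_d^T V_d = I_d`` holds after the repetition.

    Returns ``(V_d, V_block)`` where ``V_block`` is the d x d matrix of
    distinct rows on the rescaled (final) scale.
    """
    s = r * d
    if s > p:
        raise ValueError("r*d must not exceed p")
    G = rng.standard_normal((d, d))
    Q, R = np.linalg.qr(G)
    # sign fix for determinism: make diag(R) positive
    Q = Q * np.sign(np.diag(R))
    V_block = Q / np.sqrt(r)
    V = np.zeros((p, d))
    V[:s] = np.repeat(V_block, r, axis=0)
    return V, V_block


def solve_theta_last(
    V_block: np.ndarray, lambda_diag: np.ndarray, theta_free: np.ndarray
) -> float:
    """Solve the last component of ``Theta`` so the final feature block
    has exactly zero marginal covariance with the response.

    The block rows of ``Phi = V_d Lambda_d Theta`` are multiples of
    ``V_block Lambda_d Theta``; setting the d-th entry of that vector to
    zero gives

        Theta_d = - (sum_{i<d} V_block[d,i] lambda_i theta_i)
                  / (V_block[d,d] lambda_d)

    Raises if the denominator vanishes (the caller redraws ``V_block``).
    """
    V_block = np.asarray(V_block, dtype=float)
    lam = np.asarray(lambda_diag, dtype=float)
    theta_free = np.asarray(theta_free, dtype=float)
    d = V_block.shape[0]
    denom = V_block[d - 1, d - 1] * lam[d - 1]
    if abs(denom) < 1e-12:
        raise ZeroDivisionError("degenerate loading row: (d,d) entry is zero")
    num = float(np.dot(V_block[d - 1, : d - 1] * lam[: d - 1], theta_free))
    return -num / denom


def calibrate_noise(
    params: FactorModelParams,
    lambda_diag: np.ndarray,
    V_d: np.ndarray,
    Theta: np.ndarray,
) -> tuple[float, float, np.ndarray]:
    """SNR calibration of the noise scales.

    ``sigma_x^2 = tr(Lambda_d^2) / (p SNR_x^2)``; then with
    ``beta* = V_d L_d^{-1} Lambda_d Theta`` (``L_d = Lambda_d^2 +
    sigma_x^2 I``),
    ``sigma_y^2 = (beta*^T V_d Lambda_d^2 V_d^T beta*
    + sigma_x^2 ||beta*||^2) / (n SNR_y^2)``.

    Infinite SNRs give exactly zero noise.  Returns
    ``(sigma_x, sigma_y, beta_star)``.
    """
    lam = np.asarray(lambda_diag, dtype=float)
    if np.isinf(params.snr_x):
        sigma_x2 = 0.0
    else:
        sigma_x2 = float(np.sum(lam**2) / (params.p * params.snr_x**2))
    L_d = lam**2 + sigma_x2
    beta_star = V_d @ (lam / L_d * Theta)
    if np.isinf(params.snr_y):
        sigma_y2 = 0.0
    else:
        w = V_d.T @ beta_star
        signal = float(w @ (lam**2 * w) + sigma_x2 * beta_star @ beta_star)
        sigma_y2 = signal / (params.n * params.snr_y**2)
    return float(np.sqrt(sigma_x2)), float(np.sqrt(sigma_y2)), beta_star


def _assemble(params, rng, n_rows, U, E, z, V_d, Theta, sigma_x, sigma_y,
              beta_star, lam) -> SyntheticDataset:
    X = U @ (lam[:, None] * V_d.T) + sigma_x * E
    y = U @ Theta + sigma_y * z
    Phi = V_d @ (lam * Theta)
    s = params.s
    return SyntheticDataset(
        X=X,
        y=y,
        V_d=V_d,
        Theta=Theta,
        beta_star=beta_star,
        Phi=Phi,
        sigma_x=sigma_x,
        sigma_y=sigma_y,
        support=np.arange(s),
        phi_zero_group=np.arange((params.d - 1) * params.r,
                                 params.d * params.r),
        lambda_diag=lam,
        params=params,
        U=U,
    )


def _draw_truth(params: FactorModelParams, rng: np.random.Generator):
    """Loadings, Theta (with the zero-correlation construction) and the
    SNR-calibrated noise scales; redraws a degenerate loading block."""
    lam = params.lambdas()
    if lam.size != params.d:
        raise ValueError("lambda_diag must have length d")
    for attempt in range(100):
        V_d, V_block = build_loadings(params.p, params.d, params.r, rng)
        theta_free = rng.standard_normal(params.d - 1)
        try:
            theta_last = solve_theta_last(V_block, lam, theta_free)
            break
        except ZeroDivisionError:
            logger.info("degenerate loading draw (attempt %d); redrawing",
                        attempt)
    else:  # pragma: no cover - probability zero in practice
        raise RuntimeError("could not draw a non-degenerate loading matrix")
    Theta = np.append(theta_free, theta_last)
    sigma_x, sigma_y, beta_star = calibrate_noise(params, lam, V_d, Theta)
    return lam, V_d, Theta, sigma_x, sigma_y, beta_star


def generate(params: FactorModelParams) -> SyntheticDataset:
    """Draw a dataset from the row-sparse factor model.

    Deterministic given ``params.seed``.  If the loading draw makes the
    zero-correlation construction degenerate (vanishing denominator) the
    loading block is redrawn and the event logged.
    """
    rng = np.random.default_rng(params.seed)
    n, p, d = params.n, params.p, params.d

    U = rng.standard_normal((n, d))
    E = rng.standard_normal((n, p))
    z = rng.standard_normal(n)
    lam, V_d, Theta, sigma_x, sigma_y, beta_star = _draw_truth(params, rng)
    return _assemble(params, rng, n, U, E, z, V_d, Theta, sigma_x, sigma_y,
                     beta_star, lam)


def generate_learning_curve(
    params: FactorModelParams,
    n_values,
    n_test: int | None = None,
    snr_per_n: bool = True,
) -> list[tuple[SyntheticDataset, SyntheticDataset]]:
    """Nested (train, test) pairs of increasing training size from one
    population.

    The truth (loadings, Theta, beta*, sigma_x) is drawn once; the
    training sets are nested prefixes of ``max(n_values) + n_test``
    common observations and the test set is the disjoint tail, so the
    comparison across sizes uses common random numbers and isolates the
    effect of ``n``.

    With ``snr_per_n`` (the default) the response noise is recalibrated
    at every training size so the signal-to-noise ratio — not the noise
    variance — is held at ``params.snr_y``, exactly as the generator
    does at a single size; the shared test draw is scaled with the same
    ``sigma_y(n)``.  With ``snr_per_n=False`` the noise level of the
    reference size ``params.n`` is used everywhere.
    """
    n_values = sorted(int(n) for n in n_values)
    if n_test is None:
        n_test = params.n
    rng = np.random.default_rng(params.seed)
    n_big = n_values[-1] + n_test
    p, d = params.p, params.d
    U = rng.standard_normal((n_big, d))
    E = rng.standard_normal((n_big, p))
    z = rng.standard_normal(n_big)
    lam, V_d, Theta, sigma_x, sigma_y_ref, beta_star = _draw_truth(params, rng)

    X_all = U @ (lam[:, None] * V_d.T) + sigma_x * E
    signal_y = U @ Theta
    Phi = V_d @ (lam * Theta)
    w = V_d.T @ beta_star
    signal_var = float(w @ (lam**2 * w) + sigma_x**2 * beta_star @ beta_star)

    def make(rows: np.ndarray, sigma_y: float) -> SyntheticDataset:
        return SyntheticDataset(
            X=X_all[rows],
            y=signal_y[rows] + sigma_y * z[rows],
            V_d=V_d,
            Theta=Theta,
            beta_star=beta_star,
            Phi=Phi,
            sigma_x=sigma_x,
            sigma_y=sigma_y,
            support=np.arange(params.s),
            phi_zero_group=np.arange((d - 1) * params.r, d * params.r),
            lambda_diag=lam,
            params=params,
            U=U[rows],
        )

    test_rows = np.arange(n_values[-1], n_big)
    pairs = []
    for n in n_values:
        if snr_per_n and not np.isinf(params.snr_y):
            sigma_y = float(np.sqrt(signal_var / (n * params.snr_y**2)))
        else:
            sigma_y = sigma_y_ref
        pairs.append((make(np.arange(n), sigma_y), make(test_rows, sigma_y)))
    return pairs


def generate_splits(
    params: FactorModelParams,
) -> tuple[SyntheticDataset, SyntheticDataset, SyntheticDataset]:
    """Three equal-sized sets (train/validation/test) from one population:
    a single draw of the truth, ``3n`` independent observations, split."""
    big = FactorModelParams(
        n=3 * params.n,
        p=params.p,
        d=params.d,
        r=params.r,
        snr_x=params.snr_x,
        snr_y=params.snr_y,
        seed=params.seed,
        lambda_diag=params.lambda_diag,
    )
    # sigma_y is calibrated at the *per-set* n, as in the stated design
    ds = generate(big)
    if not np.isinf(params.snr_y):
        w = ds.V_d.T @ ds.beta_star
        signal = float(
            w @ (ds.lambda_diag**2 * w) + ds.sigma_x**2 * ds.beta_star @ ds.beta_star
        )
        sigma_y = float(np.sqrt(signal / (params.n * params.snr_y**2)))
        if ds.sigma_y > 0:
            noise = (ds.y - ds.U @ ds.Theta) / ds.sigma_y
        else:  # pragma: no cover
            noise = np.zeros_like(ds.y)
        ds.y = ds.U @ ds.Theta + sigma_y * noise
        ds.sigma_y = sigma_y
    n = params.n
    idx = np.arange(3 * n)
    train = ds.subset(idx[:n])
    val = ds.subset(idx[n : 2 * n])
    test = ds.subset(idx[2 * n :])
    for part in (train, val, test):
        part.params = params
    return train, val, test


def screening_fnr(
    precision: np.ndarray | sp.spmatrix,
    phi: np.ndarray,
    keep_rule=None,
    zero_tol: float = 0.0,
) -> tuple[float, float]:
    """False-negative rate of marginal screening against ``beta* =
    precision @ phi``.

    ``precision`` may be a dense matrix, a scipy sparse matrix, or a 1-D
    array of diagonal entries.  ``keep_rule(phi)`` returns the boolean
    mask of features kept by the screen (default: nonzero ``phi``).
    Returns ``(fnr, pct_nonzero_beta)`` where the second value is
    ``100 * #{beta*_j != 0} / p``.
    """
    phi = np.asarray(phi, dtype=float).ravel()
    p = phi.size
    precision_arr = precision
    if sp.issparse(precision_arr):
        beta = np.asarray(precision_arr @ phi).ravel()
    else:
        precision_arr = np.asarray(precision_arr, dtype=float)
        if precision_arr.ndim == 1:
            if precision_arr.size != p:
                raise ValueError("diagonal precision has wrong length")
            beta = precision_arr * phi
        else:
            beta = precision_arr @ phi
    kept = (phi != 0.0) if keep_rule is None else np.asarray(keep_rule(phi), bool)
    nonzero = np.abs(beta) > zero_tol
    n_nonzero = int(nonzero.sum())
    if n_nonzero == 0:
        raise ValueError("beta* has no nonzero entries; FNR undefined")
    fnr = float(np.sum(nonzero & ~kept) / n_nonzero)
    pct = 100.0 * n_nonzero / p
    return fnr, pct


def semi_synthetic(
    X_real: np.ndarray,
    d: int,
    top_rows: int,
    snr_x: float = 5.0,
    snr_y: float = 5.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Semi-synthetic data: a row-sparse factor model extracted from a
    real expression matrix.

    The sample covariance of (column-centered) ``X_real`` is
    eigendecomposed; all but the ``top_rows`` largest-norm rows of the
    leading ``d`` eigenvectors are zeroed; the basis is
    re-orthonormalized; factor scales are the square roots of the top
    empirical eigenvalues; and X and y are then rebuilt exactly as in
    :func:`generate` with the same SNR calibration.  Here ``Theta`` is
    drawn fully at random (no zero-correlation block: the empirical
    basis has no repeated-row group structure to support it).
    """
    X_real = np.asarray(X_real, dtype=float)
    n, p = X_real.shape
    if d > min(n, p):
        raise ValueError("d exceeds the dimensions of X_real")
    if top_rows > p:
        raise ValueError("top_rows exceeds the number of features")
    rng = np.random.default_rng(seed)

    Xc = X_real - X_real.mean(axis=0)
    C = Xc.T @ Xc / n
    evals, evecs = np.linalg.eigh(C)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    if evals[d - 1] <= 1e-10 * max(evals[0], 1.0):
        raise ValueError(f"X_real has rank < d = {d}")
    V = evecs[:, :d]
    norms = np.einsum("ij,ij->i", V, V)
    keep = np.argsort(-norms, kind="stable")[:top_rows]
    mask = np.zeros(p, dtype=bool)
    mask[keep] = True
    V = np.where(mask[:, None], V, 0.0)
    Q, R = np.linalg.qr(V)
    # Householder QR leaves ~1e-17 dust in the rows that are exactly
    # zero in V; the support must stay exact
    V_d = np.where(mask[:, None], Q * np.sign(np.diag(R)), 0.0)
    lam = np.sqrt(evals[:d])

    params = FactorModelParams(
        n=n, p=p, d=d, r=1, snr_x=snr_x, snr_y=snr_y, seed=seed,
        lambda_diag=lam,
    )
    U = rng.standard_normal((n, d))
    E = rng.standard_normal((n, p))
    z = rng.standard_normal(n)
    Theta = rng.standard_normal(d)
    sigma_x, sigma_y, beta_star = calibrate_noise(params, lam, V_d, Theta)
    X = U @ (lam[:, None] * V_d.T) + sigma_x * E
    y = U @ Theta + sigma_y * z
    Phi = V_d @ (lam * Theta)
    support = np.flatnonzero(np.einsum("ij,ij->i", V_d, V_d) > 0.0)
    return SyntheticDataset(
        X=X,
        y=y,
        V_d=V_d,
        Theta=Theta,
        beta_star=beta_star,
        Phi=Phi,
        sigma_x=sigma_x,
        sigma_y=sigma_y,
        support=support,
        phi_zero_group=np.array([], dtype=int),
        lambda_diag=lam,
        params=params,
        U=U,
    )
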