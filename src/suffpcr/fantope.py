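"""Convex sparse-PCA relaxation over the Fantope, solved by ADMM.

The Fantope ``F^d`` is the convex hull of the rank-``d`` projection
matrices: symmetric ``p x p`` matrices with eigenvalues in ``[0, 1]`` and
trace ``d``.  The estimator maximizes ``tr(S P) - lam * ||P||_{1,1}`` over
``P in F^d`` (Fantope Projection and Selection, FPS).  The ADMM loop
alternates a Euclidean projection onto the Fantope, an elementwise
soft-threshold, and a dual update.

The projection is computed from a *truncated* eigendecomposition: the
clipping ``min(max(e_i - tau, 0), 1)`` zeroes every eigenvalue below
``tau``, so once the smallest retained clipped value is exactly zero all
omitted eigenpairs are certified to contribute nothing and the partial
result equals the dense one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.linalg import ArpackError, ArpackNoConvergence, eigsh, lobpcg

__all__ = [
    "FantopePoint",
    "ADMMState",
    "InsufficientSpectrumError",
    "solve_tau",
    "soft_threshold",
    "fantope_project",
    "fps_admm",
]


class InsufficientSpectrumError(ValueError):
    """Fewer than ``d`` eigenvalues supplied: the clipped spectrum cannot
    sum to ``d`` even as ``tau -> -inf``.  The caller should enlarge the
    partial decomposition."""


@dataclass
class FantopePoint:
    """A point of the Fantope ``F^d``: eigenvalues in [0, 1], trace d."""

    A: np.ndarray
    d: int
    tau: float = np.nan
    eigenvalues: np.ndarray | None = None  # eigenvalues actually computed
    leading_vector: np.ndarray | None = None  # warm start for the next call
    basis: np.ndarray | None = None  # top eigenvector block (warm start)
    k_used: int = 0
    n_active: int = 0  # eigenvalues with nonzero clipped value

    def validate(self, eig_tol: float = 1e-8, trace_tol: float = 1e-6) -> None:
        if not np.allclose(self.A, self.A.T, atol=1e-10, rtol=0.0):
            raise ValueError("Fantope point is not symmetric")
        w = np.linalg.eigvalsh(self.A)
        if w.min() < -eig_tol or w.max() > 1.0 + eig_tol:
            raise ValueError(f"eigenvalues outside [0, 1]: [{w.min()}, {w.max()}]")
        if abs(np.trace(self.A) - self.d) > trace_tol:
            raise ValueError(f"trace {np.trace(self.A)} != d = {self.d}")


@dataclass
class ADMMState:
    """Diagnostics of an FPS ADMM run.

    ``primal_gap`` is ``max|A - B|`` at exit; ``B_change`` the last
    ``max|B_t - B_{t-1}|``.  ``C`` is kept so a path over ``lam`` can warm
    start from the previous solution.
    """

    iterations: int
    primal_gap: float
    B_change: float
    converged: bool
    C: np.ndarray = field(repr=False, default=None)
    k_last: int = 0
    zero_stalled: bool = False
    B_last: np.ndarray = field(repr=False, default=None)
    tail_averaged: bool = False


def solve_tau(eigs: np.ndarray, d: int) -> float:
    """Solve ``sum_i min(max(eigs_i - tau, 0), 1) = d`` for ``tau``.

    The left side is continuous, piecewise linear and non-increasing in
    ``tau``; the root is found by bisection on
    ``[min(eigs) - 1, max(eigs)]`` to 1e-12.  On a flat interval of
    solutions any point is returned (the clipped values are identical).
    """
    eigs = np.asarray(eigs, dtype=float).ravel()
    if d < 1:
        raise ValueError("d must be a positive integer")
    if eigs.size < d:
        raise InsufficientSpectrumError(
            f"{eigs.size} eigenvalues cannot carry clipped mass d={d}"
        )

    def total(tau: float) -> float:
        return float(np.minimum(np.maximum(eigs - tau, 0.0), 1.0).sum())

    lo = float(eigs.min()) - 1.0  # total(lo) = len(eigs) >= d
    hi = float(eigs.max())  # total(hi) = 0 <= d
    if total(lo) < d - 1e-12:
        raise InsufficientSpectrumError("clipped spectrum cannot reach d")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if total(mid) >= d:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-12:
            break
    tau = 0.5 * (lo + hi)
    return tau


def soft_threshold(M: np.ndarray) -> np.ndarray:
    """Elementwise ``sign(b) * max(|b| - 1, 0)`` (threshold fixed at 1;
    the penalty level enters the iteration through ``S / lam``)."""
    M = np.asarray(M, dtype=float)
    return np.sign(M) * np.maximum(np.abs(M) - 1.0, 0.0)


def _dense_spectrum(Q: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray, float]:
    w, U = eigh(Q)
    w, U = w[::-1], U[:, ::-1]
    tau = solve_tau(w, d)
    return w, U, tau


def _try_lobpcg(Qs: np.ndarray, W: np.ndarray) -> tuple | None:
    """Warm-started block eigensolve; returns (w, U) descending or None
    if the residuals are not small enough to trust.

    The iteration budget is deliberately tiny: with the previous ADMM
    step's eigenvectors as the start block a handful of iterations
    suffice, and when they do not, ARPACK (then dense) is cheaper than
    letting LOBPCG grind."""
    p = Qs.shape[0]
    if W.shape[1] >= p // 10:
        return None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, U = lobpcg(Qs, W, tol=1e-7, maxiter=10, largest=True)
    except Exception:  # noqa: BLE001 - any failure falls back to ARPACK
        return None
    if not np.all(np.isfinite(w)) or not np.all(np.isfinite(U)):
        return None
    res = Qs @ U - U * w
    scale = max(float(np.abs(w).max()), 1.0)
    if np.linalg.norm(res, axis=0).max() > 2e-6 * scale:
        return None
    order = np.argsort(w)[::-1]
    return w[order], U[:, order]


def fantope_project(
    Q: np.ndarray,
    d: int,
    k_init: int | None = None,
    v0: np.ndarray | None = None,
    warm_basis: np.ndarray | None = None,
    asym_tol: float = 1e-6,
    eig_tol: float = 0.0,
) -> FantopePoint:
    """Euclidean projection of a symmetric matrix onto the Fantope ``F^d``.

    Only the ``k`` largest eigenpairs are computed (ARPACK), with ``k``
    grown as ``k <- min(2k, p)`` until the smallest retained clipped
    eigenvalue is exactly zero — the certificate that all omitted
    eigenpairs are clipped to zero too.  Falls back to a dense
    eigendecomposition when ``k`` reaches ``p`` or ARPACK fails.

    Parameters
    ----------
    Q : (p, p) array
        Symmetric argument (symmetrized defensively as ``(Q + Q.T)/2``;
        rejected if the asymmetry exceeds ``asym_tol`` on the scale of Q).
    d : int
        Target subspace dimension, ``1 <= d < p``.
    k_init : int, optional
        Starting number of eigenpairs; default ``max(2d, d + 10)``.
    v0 : (p,) array, optional
        Deterministic start vector for the iterative eigensolver
        (typically the leading eigenvector from the previous ADMM step).
    warm_basis : (p, k) array, optional
        Eigenvector block from the previous projection of a slowly
        varying argument; tried first with a block solver.
    eig_tol : float
        Relative accuracy passed to the iterative eigensolver (0 means
        machine precision).  Inside the ADMM loop a tolerance of ~1e-8
        is ample; standalone projections default to full accuracy.
    """
    Q = np.asarray(Q, dtype=float)
    p = Q.shape[0]
    if Q.ndim != 2 or Q.shape[1] != p:
        raise ValueError("Q must be a square matrix")
    if not 1 <= d < p:
        raise ValueError(f"need 1 <= d < p, got d={d}, p={p}")
    asym = np.max(np.abs(Q - Q.T))
    if asym > asym_tol * (1.0 + np.max(np.abs(Q))):
        raise ValueError(f"Q is not symmetric (max|Q - Q.T| = {asym:.3g})")
    Qs = 0.5 * (Q + Q.T)

    if k_init is None:
        k_init = max(2 * d, d + 10)
    k = int(min(max(k_init, d + 1), p))
    if v0 is None:
        # ARPACK would otherwise draw a random start: keep runs
        # reproducible with a fixed, generic start vector
        v0 = np.random.default_rng(0).standard_normal(p)

    def certified(w_part: np.ndarray) -> float | None:
        """tau if the truncated spectrum certifies the projection."""
        try:
            tau_part = solve_tau(w_part, d)
        except InsufficientSpectrumError:
            return None
        if min(max(w_part[-1] - tau_part, 0.0), 1.0) == 0.0:
            return tau_part
        return None

    w = U = None
    tau = None
    if k >= p or p <= 64:
        # small problems: one dense decomposition beats any iteration
        w, U, tau = _dense_spectrum(Qs, d)
    if tau is None and warm_basis is not None and warm_basis.shape[0] == p:
        got = _try_lobpcg(Qs, warm_basis)
        if got is not None:
            tau = certified(got[0])
            if tau is not None:
                w, U = got
    while tau is None:
        if k >= p:
            w, U, tau = _dense_spectrum(Qs, d)
            break
        try:
            w, U = eigsh(Qs, k=k, which="LA", v0=v0, tol=eig_tol)
        except (ArpackError, ArpackNoConvergence):
            w, U, tau = _dense_spectrum(Qs, d)
            break
        order = np.argsort(w)[::-1]
        w, U = w[order], U[:, order]
        tau = certified(w)
        if tau is None:
            k = min(2 * k, p)
            if k > p // 8:
                # crowded spectrum near the clip level: further partial
                # solves would cost more than one dense decomposition
                k = p

    clipped = np.minimum(np.maximum(w - tau, 0.0), 1.0)
    keep = clipped > 0.0
    n_active = int(keep.sum())
    Uk = U[:, keep]
    A = (Uk * clipped[keep]) @ Uk.T
    A = 0.5 * (A + A.T)
    # warm-start block for the next projection: wide enough to cover the
    # active spectrum plus head-room, narrow enough for a block solver
    k_basis = min(
        U.shape[1],
        max(int(k_init), n_active + 5, d + 1),
        max(p // 10 - 1, d + 1),
    )
    return FantopePoint(
        A=A,
        d=d,
        tau=tau,
        eigenvalues=w,
        leading_vector=U[:, 0].copy(),
        basis=np.ascontiguousarray(U[:, :k_basis]),
        k_used=min(len(w), p),
        n_active=n_active,
    )


def fps_admm(
    S: np.ndarray,
    d: int,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    B0: np.ndarray | None = None,
    C0: np.ndarray | None = None,
    k_init: int | None = None,
    dense: bool = False,
    zero_stall_iters: int | None = 25,
    init: str = "zero",
    eig_tol: float = 1e-6,
    tail_average: bool = False,
) -> tuple[np.ndarray, ADMMState]:
    """FPS: maximize ``tr(S P) - lam ||P||_{1,1}`` over the Fantope by ADMM.

    Iterates, from ``B = C = 0`` (or supplied warm starts)::

        A <- Proj_{F^d}(B - C + S/lam)
        B <- Soft(A + C)
        C <- C + A - B

    and stops when ``max|A - B| <= tol`` and ``max|B_t - B_{t-1}| <= tol``,
    or at ``max_iter`` (then a non-convergence flag is set and the caller
    decides).  The soft-threshold level is fixed at 1 and the data enter
    as ``S/lam``, exactly as printed in the update equations — the ADMM
    penalty parameter is tied to ``lam``, and ``fps_admm(S, d, lam)``
    equals ``fps_admm(c S, d, c lam)``.

    Returns the sparse iterate ``B`` and an :class:`ADMMState`.

    Parameters
    ----------
    dense : bool
        Force full eigendecompositions in every projection (the O(p^3)
        reference mode, useful for verification only).
    zero_stall_iters : int or None
        Over-penalized regimes keep the soft-thresholded iterate ``B``
        identically zero for on the order of ``p/d`` iterations while
        the dual slowly accumulates (and the projection argument's flat
        spectrum forces dense decompositions).  While ``B`` has never
        left zero, the dual's sup-norm growth rate is extrapolated;
        from this iteration count on, if it cannot reach the
        soft-threshold level 1 within the remaining budget, the run
        exits early, unconverged and flagged ``zero_stalled`` — the
        caller's intercept-only fallback handles it.  ``None`` disables
        the shortcut.
    init : {"zero", "fast_forward"}
        ``"zero"`` starts from ``B = C = 0`` as printed.
        ``"fast_forward"`` replays the analytically known prefix of that
        trajectory in one step: while ``B`` stays zero the update
        degenerates to ``C <- C + A`` with ``A`` nearly constant, so the
        dual is jumped to ``C0 = A0 / max|A0|`` (one projection), which
        is where the first soft-threshold survivor appears.  Same fixed
        point, fewer iterations; ignored when ``B0``/``C0`` are given.
    eig_tol : float
        Eigensolver tolerance used inside the loop (see
        :func:`fantope_project`).
    tail_average : bool
        With the penalty parameter tied to ``lam`` as printed, the
        iterates can orbit the fixed point for a long time instead of
        settling.  The ergodic (averaged) ADMM iterate converges even
        then, so with this flag an unconverged run returns the mean of
        ``B`` over the second half of the iterations instead of the last
        iterate.  A converged run always returns the fixed point, and
        ``state.B_last`` always carries the raw final iterate (the right
        warm start for a continuation).
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if lam <= 0:
        raise ValueError("lam must be positive")
    if not 1 <= d < p:
        raise ValueError(f"need 1 <= d < p, got d={d}, p={p}")

    B = np.zeros((p, p)) if B0 is None else np.array(B0, dtype=float)
    C = np.zeros((p, p)) if C0 is None else np.array(C0, dtype=float)
    Slam = S / lam
    if init == "fast_forward" and B0 is None and C0 is None:
        A0 = fantope_project(Slam, d, k_init=k_init, eig_tol=eig_tol).A
        peak = float(np.max(np.abs(A0)))
        if peak > 0:
            C = A0 / peak
    elif init != "zero" and B0 is None and C0 is None:
        raise ValueError(f"unknown init {init!r}")

    v0 = None
    basis = None
    primal_gap = np.inf
    B_change = np.inf
    it = 0
    k_last = 0
    zero_stalled = False
    b_ever_nonzero = bool(B.any())
    g_stall_prev = None
    dense_streak = 0
    B_tail_sum = np.zeros((p, p)) if tail_average else None
    n_tail = 0
    k_adapt = k_init if k_init is not None else max(2 * d, d + 10)
    for it in range(1, max_iter + 1):
        # once the spectrum has proven flat, skip the doomed partial
        # attempts and go straight to the dense decomposition, probing
        # the truncated path again every 25 iterations
        force_dense = dense or (dense_streak > 0 and it % 25 != 0)
        fp = fantope_project(
            B - C + Slam, d, k_init=(p if force_dense else k_adapt), v0=v0,
            warm_basis=None if force_dense else basis, eig_tol=eig_tol,
        )
        dense_streak = dense_streak + 1 if fp.k_used >= p else 0
        if fp.k_used < p:
            # track the active spectrum so the next projection starts at
            # the right truncation width (and the warm block matches it)
            k_adapt = min(max(k_adapt // 2 + 1, fp.n_active + 5,
                              max(2 * d, d + 10)), p)
        v0 = fp.leading_vector
        basis = fp.basis
        k_last = fp.k_used
        A = fp.A
        B_new = soft_threshold(A + C)
        C = C + A - B_new
        primal_gap = float(np.max(np.abs(A - B_new)))
        B_change = float(np.max(np.abs(B_new - B)))
        B = B_new
        if tail_average and it > max_iter // 2:
            B_tail_sum += B
            n_tail += 1
        if primal_gap <= tol and B_change <= tol:
            break
        b_ever_nonzero = b_ever_nonzero or bool(B.any())
        if zero_stall_iters is not None and not b_ever_nonzero:
            # B == 0, so the update left C = A + C_prev and the iterate
            # stays zero until max|C| crosses the soft-threshold level 1
            g = float(np.max(np.abs(C)))
            rate = g - g_stall_prev if g_stall_prev is not None else np.inf
            g_stall_prev = g
            if (
                it >= zero_stall_iters
                and g + max(rate, 0.0) * (max_iter - it) < 0.999
            ):
                zero_stalled = True
                break
    converged = primal_gap <= tol and B_change <= tol
    if not converged and not zero_stalled:
        warnings.warn(
            f"FPS ADMM did not converge in {max_iter} iterations "
            f"(primal gap {primal_gap:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    B_ret = B
    tail_averaged = False
    if tail_average and not converged and n_tail > 0:
        B_ret = B_tail_sum / n_tail
        tail_averaged = True
    state = ADMMState(
        iterations=it,
        primal_gap=primal_gap,
        B_change=B_change,
        converged=converged,
        C=C,
        k_last=k_last,
        zero_stalled=zero_stalled,
        B_last=B,
        tail_averaged=tail_averaged,
    )
    return B_ret, state
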