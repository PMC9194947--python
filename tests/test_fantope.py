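"""Fantope projection and FPS ADMM core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from suffpcr.fantope import (
    FantopePoint,
    InsufficientSpectrumError,
    fantope_project,
    fps_admm,
    soft_threshold,
    solve_tau,
)

from conftest import random_correlation


def clip_sum(eigs, tau):
    return float(np.minimum(np.maximum(np.asarray(eigs) - tau, 0.0), 1.0).sum())


class TestSolveTau:
    def test_symmetric_spectrum_splits_equally(self):
        tau = solve_tau(np.array([1.0, 1.0, 1.0, 1.0]), 2)
        clipped = np.clip(np.array([1.0] * 4) - tau, 0, 1)
        assert np.allclose(clipped, 0.5)
        assert clip_sum([1, 1, 1, 1], tau) == pytest.approx(2.0, abs=1e-10)

    def test_projection_spectrum_is_fixed_point(self):
        tau = solve_tau(np.array([1.0, 1.0, 0.0, 0.0]), 2)
        clipped = np.minimum(np.maximum(np.array([1, 1, 0, 0]) - tau, 0), 1)
        assert np.allclose(clipped, [1, 1, 0, 0])

    def test_satisfies_sum_equation(self):
        eigs = np.array([3.0, 1.2, 0.4, -0.5])
        tau = solve_tau(eigs, 2)
        assert clip_sum(eigs, tau) == pytest.approx(2.0, abs=1e-10)

    def test_insufficient_spectrum_signalled(self):
        with pytest.raises(InsufficientSpectrumError):
            solve_tau(np.array([5.0, 4.0]), 3)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=20),
        st.integers(1, 6),
    )
    def test_sum_equation_property(self, eigs, d):
        eigs = np.sort(np.asarray(eigs, dtype=float))[::-1]
        if eigs.size < d:
            with pytest.raises(InsufficientSpectrumError):
                solve_tau(eigs, d)
        else:
            tau = solve_tau(eigs, d)
            assert clip_sum(eigs, tau) == pytest.approx(d, abs=1e-8)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.5, 0.0), (-0.3, 0.0), (1.7, 0.7), (-2.0, -1.0), (1.0, 0.0)],
    )
    def test_scalar_values(self, value, expected):
        assert soft_threshold(np.array([[value]]))[0, 0] == pytest.approx(expected)

    def test_kills_subunit_matrix_and_keeps_symmetry(self, rng):
        M = rng.uniform(-1, 1, (6, 6))
        assert np.all(soft_threshold(M) == 0.0)
        S = rng.standard_normal((6, 6)) * 2
        S = S + S.T
        out = soft_threshold(S)
        assert np.array_equal(out, out.T)


class TestFantopeProject:
    def test_identity_projects_to_scaled_identity(self):
        A = fantope_project(np.eye(10), 3).A
        assert np.allclose(A, 0.3 * np.eye(10), atol=1e-10)

    def test_idempotent_on_projection_matrices(self, rng):
        V = np.linalg.qr(rng.standard_normal((15, 4)))[0]
        Q = V @ V.T
        A = fantope_project(Q, 4).A
        assert np.allclose(A, Q, atol=1e-9)

    def test_truncated_equals_dense(self, rng):
        G = rng.standard_normal((50, 50))
        Q = (G + G.T) / 2
        A_trunc = fantope_project(Q, 2).A
        A_dense = fantope_project(Q, 2, k_init=50).A
        assert np.max(np.abs(A_trunc - A_dense)) < 1e-8

    def test_rejects_asymmetric_argument(self, rng):
        Q = rng.standard_normal((8, 8))
        with pytest.raises(ValueError, match="symmetric"):
            fantope_project(Q, 2)

    def test_feasibility_on_random_inputs(self, rng):
        for p in (10, 30, 80):
            G = rng.standard_normal((p, p))
            Q = (G + G.T) / 2
            d = int(rng.integers(1, min(5, p)))
            fp = fantope_project(Q, d)
            fp.validate()

    def test_projection_beats_random_feasible_points(self, rng):
        """The computed projection is at least as close to Q (Frobenius)
        as thousands of random Fantope points."""
        p, d, n_points = 12, 2, 10_000
        G = rng.standard_normal((p, p))
        Q = (G + G.T) / 2
        A = fantope_project(Q, d).A
        best = np.linalg.norm(A - Q)
        for _ in range(n_points):
            U = np.linalg.qr(rng.standard_normal((p, p)))[0]
            while True:
                w = rng.uniform(0, 1, p)
                w = w * (d / w.sum())
                if w.max() <= 1.0:
                    break
            P = (U * w) @ U.T
            assert np.linalg.norm(P - Q) >= best - 1e-9


def reference_tau(eigs, d):
    """Breakpoint-walking solver for the piecewise-linear clip equation
    (independent of the bisection implementation)."""
    eigs = np.asarray(eigs, dtype=float)
    breaks = np.unique(np.concatenate([eigs, eigs - 1.0]))
    lo = breaks.min() - 1.0
    for hi in list(breaks) + [breaks.max() + 1.0]:
        f_lo, f_hi = clip_sum(eigs, lo), clip_sum(eigs, hi)
        if f_hi <= d <= f_lo:
            if f_lo == f_hi:
                return lo
            return lo + (f_lo - d) * (hi - lo) / (f_lo - f_hi)
        lo = hi
    raise AssertionError("no solution bracket found")


def reference_fps_admm(S, d, lam, n_iter):
    """Literal dense-eigendecomposition transcription of the three ADMM
    update lines, run for a fixed iteration count."""
    p = S.shape[0]
    B = np.zeros((p, p))
    C = np.zeros((p, p))
    for _ in range(n_iter):
        Q = B - C + S / lam
        Q = (Q + Q.T) / 2
        w, U = np.linalg.eigh(Q)
        tau = reference_tau(w, d)
        A = (U * np.minimum(np.maximum(w - tau, 0.0), 1.0)) @ U.T
        A = (A + A.T) / 2
        B = np.sign(A + C) * np.maximum(np.abs(A + C) - 1.0, 0.0)
        C = C + A - B
    return B


class TestFpsAdmm:
    def test_matches_literal_transcription(self, rng):
        S = random_correlation(rng, 30)
        n_iter = 40
        B, state = fps_admm(S, 2, lam=0.1, tol=0.0, max_iter=n_iter,
                            zero_stall_iters=None)
        B_ref = reference_fps_admm(S, 2, 0.1, n_iter)
        assert state.iterations == n_iter
        assert np.max(np.abs(B - B_ref)) < 1e-8

    def test_complete_shrinkage_returns_zero(self, rng):
        """Over-penalized regime: every entry of A + C stays below the
        soft-threshold level for the whole iteration budget, so the
        sparse iterate never leaves zero."""
        S = random_correlation(rng, 200)
        B, state = fps_admm(S, 2, lam=1e6, tol=1e-6, max_iter=60)
        assert not B.any()
        assert state.zero_stalled or not state.converged

    def test_noiseless_rank_d_recovery(self, rng):
        """With S from noiseless rank-d data, small lam recovers the
        true eigenspace (principal angles ~ 0)."""
        p, d, r = 40, 2, 4
        Vb = np.linalg.qr(rng.standard_normal((d, d)))[0] / np.sqrt(r)
        V = np.zeros((p, d))
        V[: r * d] = np.repeat(Vb, r, axis=0)
        lam_diag = np.array([2.0, 1.0])
        U = rng.standard_normal((500, d))
        X = U @ (lam_diag[:, None] * V.T)
        S = X.T @ X / X.shape[0]
        B, _ = fps_admm(S, d, lam=1e-3, tol=1e-8, max_iter=300)
        w, Ub = np.linalg.eigh(B)
        top = Ub[:, -d:]
        sv = np.linalg.svd(top.T @ V, compute_uv=False)
        angles = np.arccos(np.clip(sv, -1, 1))
        assert np.max(angles) < 1e-3

    def test_sparsity_monotone_in_lam(self, rng):
        S = random_correlation(rng, 25)
        nnz = []
        for lam in np.geomspace(1.0, 0.01, 5):
            B, _ = fps_admm(S, 2, lam=lam, tol=1e-7, max_iter=200,
                            zero_stall_iters=None)
            nnz.append(np.count_nonzero(B))
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))

    def test_scale_coupling(self, rng):
        """The iteration depends on S/lam only: scaling both S and lam
        leaves the solution unchanged."""
        S = random_correlation(rng, 20)
        B1, _ = fps_admm(S, 2, lam=0.2, tol=1e-8, max_iter=100)
        B2, _ = fps_admm(3.0 * S, 2, lam=0.6, tol=1e-8, max_iter=100)
        assert np.max(np.abs(B1 - B2)) < 1e-9

    def test_rejects_bad_penalty(self, rng):
        S = random_correlation(rng, 10)
        with pytest.raises(ValueError):
            fps_admm(S, 2, lam=0.0)

    def test_fantope_feasibility_of_projection_iterates(self, rng):
        """Every Fantope projection along the run satisfies the
        eigenvalue and trace constraints."""
        S = random_correlation(rng, 15)
        for lam in (0.5, 0.1):
            Q = S / lam
            fp = fantope_project(Q, 3)
            fp.validate()
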