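"""Automatic row-energy thresholding of an estimated basis.

The convex relaxation tends to return a basis whose rows are entrywise
small but rarely exactly zero.  The per-feature subspace energies
``l_j = (V V^T)_{jj}`` (squared row norms) typically show a strong
elbow separating signal rows from a noise floor, like a scree plot.  The
elbow is located by comparing the observation-weighted variances on the
two sides of each candidate split and looking for the first jump in the
empirical derivative of that statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RowEnergyProfile",
    "SparseSubspace",
    "EmptySupportError",
    "row_energies",
    "elbow_threshold",
    "apply_row_threshold",
]


class EmptySupportError(ValueError):
    """Every row of the basis was thresholded to zero."""


@dataclass
class RowEnergyProfile:
    """Per-feature subspace energies sorted in descending order.

    ``energies[k]`` is the squared row norm of the feature originally at
    index ``feature_order[k]``.  Ties are broken by original feature
    order (stable sort), so the profile is deterministic.
    """

    energies: np.ndarray
    feature_order: np.ndarray

    @classmethod
    def from_basis(cls, V: np.ndarray) -> "RowEnergyProfile":
        l = row_energies(V)
        order = np.argsort(-l, kind="stable")
        return cls(energies=l[order], feature_order=order)


@dataclass
class SparseSubspace:
    """A p x d basis with an explicit row-support set.

    Rows outside ``support`` are exactly zero; ``support`` holds the
    original indices of the rows with nonzero norm, in increasing order.
    """

    V: np.ndarray
    support: np.ndarray
    threshold: float

    @property
    def n_selected(self) -> int:
        return int(self.support.size)


def row_energies(V: np.ndarray) -> np.ndarray:
    """``diag(V V^T)``: squared Euclidean norm of each row of V."""
    V = np.asarray(V, dtype=float)
    return np.einsum("ij,ij->i", V, V)


def _segment_variances(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample variances (ddof=1) of all prefixes and suffixes of ``x``.

    ``prefix[i]`` is var(x[:i+1]); ``suffix[i]`` is var(x[i+1:]).
    Segments of length < 2 have variance 0 by convention.
    """
    p = x.size
    idx = np.arange(1, p + 1, dtype=float)
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    prefix = np.zeros(p)
    m = idx > 1
    prefix[m] = (c2[m] - c1[m] ** 2 / idx[m]) / (idx[m] - 1.0)
    r1 = c1[-1] - c1
    r2 = c2[-1] - c2
    rn = p - idx
    suffix = np.zeros(p)
    m = rn > 1
    suffix[m] = (r2[m] - r1[m] ** 2 / rn[m]) / (rn[m] - 1.0)
    return np.maximum(prefix, 0.0), np.maximum(suffix, 0.0)


def elbow_threshold(l: np.ndarray | RowEnergyProfile) -> tuple[float, int]:
    """Locate the signal/noise elbow in a row-energy profile.

    With 1-based positions ``i`` over the descending-sorted energies::

        Tn[i]    = var(l[1..i])          (left, "signal" side)
        Ts[i]    = var(l[i+1..p])        (right, "noise" side)
        T[i]     = i * Tn[i] + (p - i) * Ts[i]
        delta[i] = T[i] - T[i-1]         (empirical derivative, delta[1] := 0)

    and ``i*`` is the smallest ``i in {3, ..., p}`` with
    ``delta[i] - delta[i-1] > mean(|delta[1..i-1]|)``.  Returns
    ``(t, i*)`` with ``t = l[i*]``; rows with energy strictly below ``t``
    are candidates for zeroing.  If no index qualifies — or the profile
    is constant or has fewer than 4 entries — returns ``(0.0, p)`` so
    every row is kept.
    """
    if isinstance(l, RowEnergyProfile):
        ls = np.asarray(l.energies, dtype=float)
    else:
        ls = np.sort(np.asarray(l, dtype=float))[::-1]
    p = ls.size
    if p < 4:
        warnings.warn(
            f"row-energy profile of length {p} < 4: keeping all rows",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0, p
    if ls[0] - ls[-1] <= 1e-10 * max(ls[0], 1e-300):
        return 0.0, p  # numerically constant profile: nothing to split

    Tn, Ts = _segment_variances(ls)
    i = np.arange(1, p + 1, dtype=float)
    T = i * Tn + (p - i) * Ts
    delta = np.zeros(p)
    delta[1:] = np.diff(T)  # delta[0] (i=1) := 0
    # floor below which a jump is floating-point noise, not structure
    eps = 1e-12 * max(float(np.max(np.abs(T))), 1e-300)

    # running mean of |delta[1..i-1]| without an O(p^2) rescan
    abs_cum = np.cumsum(np.abs(delta))
    for pos in range(2, p):  # pos is 0-based; i = pos + 1 ranges over 3..p
        jump = delta[pos] - delta[pos - 1]
        mean_prev = abs_cum[pos - 1] / pos
        if jump > mean_prev + eps:
            return float(ls[pos]), pos + 1
    return 0.0, p


def apply_row_threshold(V: np.ndarray, t: float) -> SparseSubspace:
    """Zero every row of ``V`` whose energy (squared row norm, the scale
    of the elbow profile) is strictly below ``t``.

    The recorded support is the set of rows with nonzero norm after
    thresholding, so rows that were exactly zero already are excluded
    even when ``t = 0``.
    """
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    V = np.array(V, dtype=float)
    l = row_energies(V)
    V[l < t] = 0.0
    support = np.flatnonzero(row_energies(V) > 0.0)
    if support.size == 0:
        raise EmptySupportError("row threshold removed every feature")
    return SparseSubspace(V=V, support=support, threshold=float(t))
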