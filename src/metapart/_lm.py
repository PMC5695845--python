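"""Shared least-squares helpers for redundancy analysis and permutation tests.

Everything downstream works on column-centered arrays (the intercept is
implicit) and on orthonormal bases of predictor spans, so explained sums of
squares reduce to norms of projections.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

__all__ = ["as_matrix", "center", "orthonormal_basis", "rank_and_pivots"]


def as_matrix(a) -> np.ndarray:
    """Coerce a vector/matrix/DataFrame to a 2-D float array (n × q)."""
    arr = np.asarray(getattr(a, "values", a), dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1)
    if arr.ndim != 2:
        raise ValueError(f"expected 1-D or 2-D input, got shape {arr.shape}")
    return arr


def center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def orthonormal_basis(x: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space of ``x`` (rank-revealing QR)."""
    if x.size == 0:
        return np.zeros((x.shape[0], 0))
    q, r, _ = scipy.linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > tol * max(diag.max(), 1e-300)))
    return q[:, :rank]


def rank_and_pivots(x: np.ndarray, tol: float = 1e-10) -> tuple[int, np.ndarray]:
    """Numerical rank plus the QR column pivots (dependent columns last)."""
    if x.size == 0:
        return 0, np.array([], dtype=int)
    _, r, piv = scipy.linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > tol * max(diag.max(), 1e-300)))
    return rank, piv
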