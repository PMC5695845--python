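"""PCNM spatial eigenfunctions and Moran's I screening.

Principal Coordinates of Neighbour Matrices (PCNM): the pairwise Euclidean
distance matrix between plots is truncated at a connectivity threshold t
(distances beyond t replaced by 4t), double-centered, and eigendecomposed.
Eigenvectors associated with positive eigenvalues describe spatial patterns
from broad scale (large eigenvalues) to fine scale.  Candidate spatial
predictors are the eigenvectors that both have a positive eigenvalue and show
positive, significant spatial autocorrelation by a permutation test of
Moran's I on the truncation-graph connectivity weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SpatialEigenbasis",
    "distance_matrix",
    "truncation_threshold",
    "pcnm",
    "morans_i",
    "morans_expectation",
    "screen_eigenbasis",
    "connectivity_weights",
    "validate_projected",
]

log = logging.getLogger(__name__)

#: distances beyond the threshold are replaced by this multiple of t
TRUNCATION_FILL_FACTOR = 4.0


def distance_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between plots (meters in, meters out)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least 2 plots with coordinate pairs")
    d = squareform(pdist(coords))
    dup = (d + np.eye(len(d)) == 0).any()
    if dup:
        log.warning("duplicate coordinates: zero off-diagonal distances present")
    return d


def validate_projected(coords: np.ndarray) -> None:
    """Reject coordinates that look like geographic lat/lon degrees.

    PCNM needs a projected metric system; a point cloud whose values all fit
    inside the ±180/±90 degree box and whose spread is a few units at most is
    almost certainly unprojected.
    """
    coords = np.asarray(coords, dtype=float)
    x, y = coords[:, 0], coords[:, 1]
    in_degree_box = np.abs(x).max() <= 180 and np.abs(y).max() <= 90
    tiny_spread = max(np.ptp(x), np.ptp(y)) <= 10
    if in_degree_box and tiny_spread:
        raise ValueError(
            "coordinates look like geographic lat/lon degrees; project to a "
            "metric system (e.g. UTM) before building spatial eigenfunctions"
        )


def truncation_threshold(d: np.ndarray) -> float:
    """Longest edge of the minimum spanning tree of the complete distance graph.

    Truncating at this distance keeps the plot network connected — the
    standard PCNM convention when no threshold is imposed.
    """
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 plots")
    mst = minimum_spanning_tree(d).toarray()
    return float(mst.max())


@dataclass
class SpatialEigenbasis:
    """PCNM eigenvectors/eigenvalues plus Moran's I screening results."""

    eigenvectors: np.ndarray  # plots × k, orthonormal columns
    eigenvalues: np.ndarray  # descending
    truncation: float
    plot_ids: list[str] | None = None
    morans_i: np.ndarray | None = None
    morans_p: np.ndarray | None = None
    retained: np.ndarray | None = None

    @property
    def n_axes(self) -> int:
        return self.eigenvectors.shape[1]

    def retained_vectors(self) -> np.ndarray:
        if self.retained is None:
            raise ValueError("eigenbasis has not been screened yet")
        return self.eigenvectors[:, self.retained]

    def axis_names(self) -> list[str]:
        return [f"PCNM{i + 1}" for i in range(self.n_axes)]


def pcnm(
    d: np.ndarray,
    t: float | None = None,
    plot_ids: list[str] | None = None,
    zero_tol: float = 1e-9,
) -> SpatialEigenbasis:
    """Principal coordinate analysis of the truncated distance matrix.

    D* keeps d_ij for d_ij ≤ t and replaces larger distances by 4t (diagonal
    stays 0); B = −½ · double-centered D*² is eigendecomposed.  Eigenvectors
    are unit-norm, ordered by descending eigenvalue, signs fixed so the
    largest-magnitude loading is positive; eigenvalues with magnitude below
    ``zero_tol`` × max |eigenvalue| are dropped as numerical zeros.
    """
    d = np.asarray(d, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if t is None:
        t = truncation_threshold(d)
    if not t > 0:
        raise ValueError("truncation threshold must be > 0")
    n = d.shape[0]
    dstar = np.where(d <= t, d, TRUNCATION_FILL_FACTOR * t)
    np.fill_diagonal(dstar, 0.0)
    a = -0.5 * dstar**2
    # Gower double-centering: subtract row and column means, add grand mean
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    b = a - row - col + a.mean()
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = np.abs(vals) > zero_tol * max(np.abs(vals).max(), np.finfo(float).tiny)
    vals, vecs = vals[keep], vecs[:, keep]
    # deterministic sign: largest-magnitude loading positive
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] *= -1.0
    return SpatialEigenbasis(
        eigenvectors=vecs, eigenvalues=vals, truncation=float(t), plot_ids=plot_ids
    )


def morans_expectation(n: int) -> float:
    """Expected Moran's I under the spatial-randomness null: −1/(n−1)."""
    return -1.0 / (n - 1)


def morans_i(
    v: np.ndarray,
    w: np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Moran's I with a one-sided (I ≥ observed) permutation p-value.

    I = (n/ΣΣw) · (ΣΣ w_ij z_i z_j) / (Σ z_i²) with z the centered values;
    ``w`` must be symmetric with zero diagonal and at least one positive
    weight.  With ``n_perm = 0`` only the statistic is returned (p = nan).
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.ptp(v) == 0:
        raise ValueError("Moran's I undefined for a constant vector")
    if not np.allclose(w, w.T) or np.abs(np.diag(w)).max() > 0:
        raise ValueError("weights must be symmetric with zero diagonal")
    s0 = w.sum()
    if not s0 > 0:
        raise ValueError("weight matrix needs at least one positive weight")
    n = len(v)
    z = v - v.mean()
    denom = float(z @ z)
    obs = float(n / s0 * (z @ w @ z) / denom)
    if n_perm == 0:
        return obs, float("nan")
    if rng is None:
        rng = np.random.default_rng()
    idx = np.argsort(rng.random((n_perm, n)), axis=1)  # n_perm random permutations
    zp = z[idx].T  # n × n_perm
    stats = n / s0 * np.einsum("ip,ip->p", zp, w @ zp) / denom
    p = (1.0 + np.sum(stats >= obs)) / (1.0 + n_perm)
    return obs, float(p)


def connectivity_weights(d: np.ndarray, t: float) -> np.ndarray:
    """Binary connectivity weights of the truncation graph: w_ij = 1 iff 0 < d_ij ≤ t."""
    w = ((d > 0) & (d <= t)).astype(float)
    np.fill_diagonal(w, 0.0)
    return w


def screen_eigenbasis(
    b: SpatialEigenbasis,
    d: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> SpatialEigenbasis:
    """Retain eigenvectors with positive eigenvalue and significant positive Moran's I.

    Moran's I uses binary connectivity at the truncation threshold; an axis is
    retained iff eigenvalue > 0, I above its null expectation −1/(n−1), and
    permutation p ≤ alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    w = connectivity_weights(d, b.truncation)
    n = b.eigenvectors.shape[0]
    e0 = morans_expectation(n)
    i_stats = np.empty(b.n_axes)
    p_vals = np.empty(b.n_axes)
    for j in range(b.n_axes):
        i_stats[j], p_vals[j] = morans_i(b.eigenvectors[:, j], w, n_perm, rng)
    retained = (b.eigenvalues > 0) & (i_stats > e0) & (p_vals <= alpha)
    return SpatialEigenbasis(
        eigenvectors=b.eigenvectors,
        eigenvalues=b.eigenvalues,
        truncation=b.truncation,
        plot_ids=b.plot_ids,
        morans_i=i_stats,
        morans_p=p_vals,
        retained=retained,
    )
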