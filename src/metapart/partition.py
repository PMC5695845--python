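"""Redundancy analysis R², adjusted R², and two-set variance partitioning.

For a (possibly multivariate) response Y and two predictor sets — selected
topographic variables E and selected spatial eigenvectors S — the adjusted
explained variance is split by inclusion–exclusion into

    a = pure topography,  b = shared,  c = pure space,  d = unexplained,

with ab = adjR²(Y~E), bc = adjR²(Y~S), abc = adjR²(Y~E∪S) and

    a = abc − bc,  c = abc − ab,  b = ab + bc − abc,  d = 1 − abc.

Adjusted R² uses the Ezekiel correction 1 − (1 − R²)(n − 1)/(n − m − 1),
which makes fractions comparable across predictor sets of different sizes
(and lets a and c go slightly negative; they are reported as computed).
Fractions a and c are testable by conditioned Freedman–Lane permutation
tests; the marginal models ab and bc by unconditioned permutation; b and d
admit no permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._lm import as_matrix, center, orthonormal_basis, rank_and_pivots
from .selection import freedman_lane_test, pseudo_f

__all__ = ["VariancePartition", "rda_r2", "varpart", "test_fraction"]


def _named_matrix(x) -> tuple[np.ndarray, list[str]]:
    if x is None:
        return np.zeros((0, 0)), []
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), [str(c) for c in x.columns]
    arr = as_matrix(x)
    return arr, [f"x{j + 1}" for j in range(arr.shape[1])]


def rda_r2(Y, X) -> tuple[float, float]:
    """Trace R² and Ezekiel-adjusted R² of the least-squares fit of Y on X.

    Each column of Y is regressed on X with intercept; R² is the explained
    share of the total (centered) sum of squares across all columns, which
    reduces to the ordinary R² for a univariate response.  An empty predictor
    set gives (0, 0).
    """
    yc = center(as_matrix(Y))
    x, names = _named_matrix(X)
    n = yc.shape[0]
    m = x.shape[1] if x.size else 0
    if m == 0:
        return 0.0, 0.0
    if n <= m + 1:
        raise ValueError(f"need n > m + 1 (n={n}, m={m})")
    xc = center(x)
    rank, piv = rank_and_pivots(xc)
    if rank < m:
        bad = [names[j] for j in piv[rank:]]
        raise np.linalg.LinAlgError(f"rank-deficient predictors; collinear columns: {bad}")
    q = orthonormal_basis(xc)
    ss_tot = float((yc**2).sum())
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    r2 = float(((q.T @ yc) ** 2).sum()) / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
    return r2, adj


def _adj_r2_by_rank(Y, x: np.ndarray) -> float:
    """Adjusted R² of Y on the span of x, with m = rank of the span."""
    yc = center(as_matrix(Y))
    n = yc.shape[0]
    q = orthonormal_basis(center(x))
    m = q.shape[1]
    if n <= m + 1:
        raise ValueError(f"need n > rank + 1 (n={n}, rank={m})")
    r2 = float(((q.T @ yc) ** 2).sum()) / float((yc**2).sum())
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


@dataclass
class VariancePartition:
    """Adjusted-R² fractions a/b/c/d with permutation p-values where testable."""

    fraction_a: float
    fraction_b: float
    fraction_c: float
    fraction_d: float
    adj_r2_e: float  # ab
    adj_r2_s: float  # bc
    adj_r2_joint: float  # abc
    p_a: float = float("nan")
    p_c: float = float("nan")
    p_ab: float = float("nan")
    p_bc: float = float("nan")
    n_env_selected: int = 0
    n_spa_selected: int = 0
    degenerate_flags: list[str] = field(default_factory=list)

    def fractions(self) -> dict[str, float]:
        return {
            "a": self.fraction_a,
            "b": self.fraction_b,
            "c": self.fraction_c,
            "d": self.fraction_d,
        }


def varpart(
    Y,
    E=None,
    S=None,
    n_perm: int = 0,
    rng: np.random.Generator | None = None,
) -> VariancePartition:
    """Two-set variance partition of ``Y`` into fractions a, b, c, d.

    Either set may be empty (its marginal adjusted R² is 0 and the partition
    degenerates accordingly).  With ``n_perm > 0``, permutation p-values are
    attached: conditional tests for a (E | S) and c (S | E), marginal tests
    for ab and bc.
    """
    e, _ = _named_matrix(E)
    s, _ = _named_matrix(S)
    m_e = e.shape[1] if e.size else 0
    m_s = s.shape[1] if s.size else 0
    flags = []
    if m_e == 0:
        flags.append("no variables selected for the environmental set")
    if m_s == 0:
        flags.append("no variables selected for the spatial set")

    _, ab = rda_r2(Y, E) if m_e else (0.0, 0.0)
    _, bc = rda_r2(Y, S) if m_s else (0.0, 0.0)
    if m_e and m_s:
        # the two sets may overlap (shared variation is the point); the joint
        # model uses the rank of the combined span for its Ezekiel correction
        abc = _adj_r2_by_rank(Y, np.column_stack([e, s]))
    else:
        abc = ab if m_e else bc

    part = VariancePartition(
        fraction_a=abc - bc,
        fraction_b=ab + bc - abc,
        fraction_c=abc - ab,
        fraction_d=1.0 - abc,
        adj_r2_e=ab,
        adj_r2_s=bc,
        adj_r2_joint=abc,
        n_env_selected=m_e,
        n_spa_selected=m_s,
        degenerate_flags=flags,
    )
    if n_perm > 0:
        if rng is None:
            rng = np.random.default_rng()
        if m_e:
            _, part.p_ab = freedman_lane_test(Y, e, None, n_perm, rng)
            if m_s:
                _, part.p_a = freedman_lane_test(Y, e, s, n_perm, rng)
            else:
                part.p_a = part.p_ab
        if m_s:
            _, part.p_bc = freedman_lane_test(Y, s, None, n_perm, rng)
            if m_e:
                _, part.p_c = freedman_lane_test(Y, s, e, n_perm, rng)
            else:
                part.p_c = part.p_bc
    return part


def test_fraction(
    Y,
    X_test,
    X_cond=None,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for the partial model Y ~ X_test | X_cond.

    Conditioned tests use Freedman–Lane residual permutation; with no
    conditioning set the permutation is a plain relabeling of response rows.
    """
    _, p = freedman_lane_test(Y, X_test, X_cond, n_perm, rng)
    return p
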