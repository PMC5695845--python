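"""Permutation-based forward selection of explanatory variables.

The protocol is the double-stopping forward selection used with constrained
ordination: a global permutation test of the full candidate model gates the
whole procedure; candidates are then added one at a time by greatest
additional explained variance, each addition tested by a Freedman–Lane
permutation pseudo-F conditioned on the variables already in the model, and
selection stops when the best candidate fails the alpha test or when the
selected model's adjusted R² reaches that of the full candidate model (the
crossing variable is retained, then selection halts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._lm import as_matrix, center, orthonormal_basis

__all__ = ["SelectionStep", "SelectionResult", "pseudo_f", "freedman_lane_test", "forward_select"]

_PERM_CHUNK = 250  # permutations processed per block (bounds peak memory)


def pseudo_f(Y, X_test, X_cond=None) -> float:
    """Pseudo-F of ``X_test`` given ``X_cond`` for a (possibly multivariate) response.

    F = (SS_test / q) / (SS_res / df_res) where SS terms are Frobenius sums of
    squares of the centered response projected onto the span of the
    residualized test predictors, q is that span's dimension and
    df_res = n − 1 − m_cond − q.  For a single-column response this is the
    classical partial F of nested linear models.
    """
    f, _ = _partial_f(
        center(as_matrix(Y)),
        as_matrix(X_test),
        None if X_cond is None else as_matrix(X_cond),
    )
    return f


def _partial_f(yc, x_test, x_cond):
    """Observed pseudo-F plus the pieces needed for permutation replicates."""
    n = yc.shape[0]
    qc = (
        orthonormal_basis(center(x_cond))
        if x_cond is not None and x_cond.shape[1] > 0
        else np.zeros((n, 0))
    )
    xt = center(x_test)
    xt_res = xt - qc @ (qc.T @ xt)
    # scale test against the *original* predictor norms, so columns absorbed
    # by the conditioning span register as gone rather than as tiny noise
    orig = np.linalg.norm(xt, axis=0)
    res = np.linalg.norm(xt_res, axis=0)
    keep = res > 1e-8 * np.maximum(orig, 1e-300)
    qt = orthonormal_basis(xt_res[:, keep]) if keep.any() else np.zeros((n, 0))
    q = qt.shape[1]
    if q == 0:
        raise np.linalg.LinAlgError(
            "test predictors are collinear with the conditioning design"
        )
    m_cond = qc.shape[1]
    df_res = n - 1 - m_cond - q
    if df_res <= 0:
        raise ValueError("not enough residual degrees of freedom")
    yr = yc - qc @ (qc.T @ yc)
    ss_tot_r = float((yr**2).sum())
    ss_test = float(((qt.T @ yr) ** 2).sum())
    rss = max(ss_tot_r - ss_test, 0.0)
    f = np.inf if rss == 0.0 else (ss_test / q) / (rss / df_res)
    return f, (yr, qc, qt, q, m_cond, df_res, ss_tot_r)


def freedman_lane_test(
    Y,
    X_test,
    X_cond=None,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation test of ``X_test | X_cond`` by residual permutation.

    Residuals of the response on the conditioning set are permuted
    (Freedman–Lane); with no conditioning set this reduces to a plain
    permutation of the response rows.  Returns ``(F_observed, p)`` with
    p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm).
    """
    if rng is None:
        rng = np.random.default_rng()
    yc = center(as_matrix(Y))
    f_obs, (yr, qc, qt, q, m_cond, df_res, ss_tot_r) = _partial_f(
        yc, as_matrix(X_test), None if X_cond is None else as_matrix(X_cond)
    )
    n = yc.shape[0]
    count = 0
    done = 0
    while done < n_perm:
        k = min(_PERM_CHUNK, n_perm - done)
        idx = np.argsort(rng.random((k, n)), axis=1)
        e = yr[idx]  # k × n × q_y permuted residual matrices
        ss_test_p = np.einsum("nk,pnq->pkq", qt, e)
        ss_test_p = (ss_test_p**2).sum(axis=(1, 2))
        if m_cond:
            ss_cond_p = np.einsum("nk,pnq->pkq", qc, e)
            ss_cond_p = (ss_cond_p**2).sum(axis=(1, 2))
        else:
            ss_cond_p = 0.0
        rss_p = np.maximum(ss_tot_r - ss_cond_p - ss_test_p, 0.0)
        with np.errstate(divide="ignore"):
            f_p = (ss_test_p / q) / (rss_p / df_res)
        count += int(np.sum(f_p >= f_obs))
        done += k
    p = (1.0 + count) / (1.0 + n_perm)
    return f_obs, p


@dataclass
class SelectionStep:
    variable: str
    pseudo_f: float
    p_value: float
    cum_adj_r2: float


@dataclass
class SelectionResult:
    """Outcome of one forward-selection run on one candidate set."""

    candidate_ids: list[str]
    selected_ids: list[str]
    steps: list[SelectionStep]
    global_adj_r2: float
    global_p: float
    dropped_ids: list[str] = field(default_factory=list)
    stopped_by: str = ""

    @property
    def n_selected(self) -> int:
        return len(self.selected_ids)


def forward_select(
    Y,
    X: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    adj_r2_tol: float = 1e-12,
) -> SelectionResult:
    """Double-stopping forward selection of columns of ``X`` for response ``Y``.

    ``X`` must be a DataFrame (column names identify variables); columns are
    standardized internally and the response is centered internally.  The
    procedure is gated on a global permutation test of the full candidate
    model at ``alpha``; it stops when the best candidate's Freedman–Lane
    p-value exceeds ``alpha`` or when adding it would push the selected
    model's adjusted R² above the full model's.
    """
    from .partition import rda_r2  # local import: partition builds on selection

    if rng is None:
        rng = np.random.default_rng()
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{j + 1}" for j in range(X.shape[1])]
    yc = center(as_matrix(Y))
    n = yc.shape[0]

    variances = X.var(axis=0, ddof=0)
    dropped = [c for c in X.columns if variances[c] == 0]
    if dropped:
        warnings.warn(f"dropping zero-variance candidate columns: {dropped}")
        X = X.drop(columns=dropped)
    candidates = list(X.columns)
    if len(candidates) > n - 1:
        raise ValueError(
            f"{len(candidates)} candidates for {n} plots: need at most n-1"
        )
    xs = center(X.to_numpy(dtype=float))
    xs = xs / xs.std(axis=0, ddof=0)
    cols = {c: xs[:, j] for j, c in enumerate(candidates)}

    if not candidates:
        return SelectionResult([], [], [], 0.0, float("nan"), dropped, "no candidates")

    _, global_adj = rda_r2(yc, X)
    _, global_p = freedman_lane_test(yc, xs, None, n_perm, rng)
    result = SelectionResult(candidates, [], [], global_adj, global_p, dropped)
    if global_p > alpha:
        result.stopped_by = "global test not significant"
        return result

    selected: list[str] = []
    while True:
        remaining = sorted(set(candidates) - set(selected))
        if not remaining:
            result.stopped_by = "all candidates selected"
            break
        x_sel = (
            np.column_stack([cols[c] for c in selected])
            if selected
            else np.zeros((n, 0))
        )
        qs = orthonormal_basis(x_sel)
        yr = yc - qs @ (qs.T @ yc)
        best, best_ss = None, -np.inf
        for c in remaining:  # id-ascending order makes the tie-break explicit
            xr = cols[c] - qs @ (qs.T @ cols[c])
            nrm = np.linalg.norm(xr)
            if nrm < 1e-10:
                continue  # collinear with current model
            u = xr / nrm
            ss = float(((u @ yr) ** 2).sum())
            if ss > best_ss:
                best, best_ss = c, ss
        if best is None:
            result.stopped_by = "remaining candidates collinear"
            break
        f, p = freedman_lane_test(
            yc, cols[best], x_sel if selected else None, n_perm, rng
        )
        if p > alpha:
            result.stopped_by = f"candidate {best!r} p={p:.4f} > alpha"
            break
        _, adj_with = rda_r2(yc, X[selected + [best]])
        selected.append(best)
        result.steps.append(SelectionStep(best, f, p, adj_with))
        if adj_with > global_adj + adj_r2_tol:
            # the crossing variable is retained, then selection stops
            result.stopped_by = (
                f"{best!r} reached the global adjusted R² ceiling"
            )
            break
    result.selected_ids = selected
    if not result.stopped_by:
        result.stopped_by = "alpha"
    return result
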