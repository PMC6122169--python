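"""Linear quantile regression by exact linear programming.

The pinball-loss minimizer is found by solving the dual LP

    max  y'd   s.t.  X'd = 0,  tau - 1 <= d_i <= tau

with HiGHS; the primal coefficients are recovered from the marginals of
the equality constraints.  This is exact (a vertex solution of the primal
polytope), unlike iteratively reweighted least squares, and fast for the
small designs used in gap-fill subsets.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def pinball_loss(y: np.ndarray, yhat: np.ndarray, tau: float) -> float:
    """Summed tau-weighted absolute residuals (the check-function loss)."""
    r = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
    return float(np.sum(np.where(r >= 0, tau * r, (tau - 1.0) * r)))


def fit_quantile(X: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Coefficients minimizing the pinball loss of ``y - X @ beta`` at ``tau``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) and y (n,) with matching n")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least {p} observations to fit {p} coefficients")
    res = linprog(
        -y,
        A_eq=X.T,
        b_eq=np.zeros(p),
        bounds=[(tau - 1.0, tau)] * n,
        method="highs",
    )
    if not res.success:  # pragma: no cover - HiGHS is robust on these LPs
        raise RuntimeError(f"quantile LP failed: {res.message}")
    return -np.asarray(res.eqlin.marginals, dtype=float)


def fit_quantiles(X: np.ndarray, y: np.ndarray, taus) -> list[np.ndarray]:
    """Fit the same design at several quantile levels."""
    return [fit_quantile(X, y, tau) for tau in taus]


def fit_quantile_brute(X: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Brute-force pinball minimizer over all basic solutions.

    Enumerates every subset of ``p`` observations, fits the exact
    interpolating hyperplane where the subset is non-singular, and keeps
    the plane of lowest loss.  Exponential: intended as an independent
    oracle for small problems (n <= ~30).
    """
    from itertools import combinations

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    best, best_loss = None, np.inf
    for idx in combinations(range(n), p):
        sub = X[list(idx)]
        if np.linalg.matrix_rank(sub) < p:
            continue
        beta, *_ = np.linalg.lstsq(sub, y[list(idx)], rcond=None)
        loss = pinball_loss(y, X @ beta, tau)
        if loss < best_loss:
            best, best_loss = beta, loss
    if best is None:
        raise ValueError("design has no non-singular basic solution")
    return best
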