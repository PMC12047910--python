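"""Adaptive transfer of the source loading matrix to the target data.

Step 2 estimates target factors V and a target loading W by minimizing the
penalized reconstruction objective

    sum_i || xtgt_i - W v_i ||^2  +  lambda * || W - W0_hat ||_F^2

which shrinks the target loading toward the source-learned W0_hat.  The
objective is biconvex; alternating exact minimization (ALS) solves each
block in closed form, so the objective is non-increasing by construction:

    V-step:  V = X W (W'W)^{-1}
    W-step:  W = (X'V + lambda W0)(V'V + lambda I)^{-1}

lambda is selected by the two-fold scheme: split the target rows evenly,
fit the penalized factorization on each fold, and score each lambda by how
well the *other* fold's rows are reconstructed after least-squares
projection onto the fitted loading's span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .core_io import ExpressionMatrix

RIDGE = 1e-8


@dataclass
class TransferFit:
    W: np.ndarray                 # (p, q) target loading
    V: np.ndarray                 # (n0, q) target factors
    lam: float
    objective_trace: np.ndarray   # per-iteration penalized objective
    cv_table: list[tuple[float, float]] | None = None
    n_iter: int = 0
    converged: bool = False


def _solve_psd(G: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve G X = B for symmetric positive (semi)definite G, with ridge."""
    try:
        c, low = linalg.cho_factor(G)
        return linalg.cho_solve((c, low), B)
    except linalg.LinAlgError:
        warnings.warn("near-singular Gram matrix; applying 1e-8 ridge",
                      stacklevel=3)
        return linalg.solve(G + RIDGE * np.eye(G.shape[0]), B, assume_a="sym")


def transfer_objective(
    X: np.ndarray, W: np.ndarray, V: np.ndarray, W0: np.ndarray, lam: float
) -> float:
    resid = X - V @ W.T
    return float(np.sum(resid * resid) + lam * np.sum((W - W0) ** 2))


def fit_transfer(
    target: ExpressionMatrix | np.ndarray,
    W0: np.ndarray,
    lam: float,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> TransferFit:
    """Alternating least squares for the penalized target factorization.

    Initialized at ``W = W0``; stops when the relative objective change
    falls below ``tol``.  Each half-step is the exact block minimizer, so
    the recorded objective trace never increases.
    """
    X = target.values if isinstance(target, ExpressionMatrix) else np.asarray(target, float)
    W0 = np.asarray(W0, dtype=float)
    p, q = W0.shape
    if X.shape[1] != p:
        raise ValueError(f"target has {X.shape[1]} genes; W0 expects {p}")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")

    W = W0.copy()
    V = np.zeros((X.shape[0], q))
    trace = []
    converged = False
    for it in range(max_iter):
        V = (_solve_psd(W.T @ W, W.T @ X.T)).T
        G = V.T @ V + lam * np.eye(q)
        if lam == 0.0:
            W = _solve_psd(G, V.T @ X).T
        else:
            W = linalg.solve(G, V.T @ X + lam * W0.T, assume_a="pos").T
        trace.append(transfer_objective(X, W, V, W0, lam))
        if it > 0 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1.0):
            converged = True
            break
    return TransferFit(
        W=W, V=V, lam=float(lam),
        objective_trace=np.asarray(trace),
        n_iter=len(trace), converged=converged,
    )


def orthonormal_factors(target: ExpressionMatrix | np.ndarray, W: np.ndarray) -> np.ndarray:
    """Target coordinates in an orthonormal basis for span(W).

    Equals ``V @ R.T`` for the QR factorization ``W = Q R``, i.e. the
    variance-carrying reparameterization of the fitted factors: the
    factorization ``V W' = (V R') Q'`` is unchanged, but the returned
    coordinates scale like PCA scores instead of being whitened.  This is
    the representation handed to clustering, whose k-means initialization
    is not affine-invariant.
    """
    X = target.values if isinstance(target, ExpressionMatrix) else np.asarray(target, float)
    Q, _ = np.linalg.qr(np.asarray(W, dtype=float))
    return X @ Q


def default_lambda_grid(n0: int, p: int, W0: np.ndarray) -> np.ndarray:
    """Scale-aware default grid {0, .01, .1, 1, 10, 100} x n0*p/(||W0||_F^2+1).

    The multiplier makes the penalty term commensurate with the data term
    across dataset sizes.
    """
    scale = n0 * p / (float(np.sum(W0 * W0)) + 1.0)
    return np.array([0.0, 0.01, 0.1, 1.0, 10.0, 100.0]) * scale


def _projection_error(X_hold: np.ndarray, W: np.ndarray) -> float:
    """Squared residual of least-squares projection of rows onto span(W)."""
    V = (_solve_psd(W.T @ W, W.T @ X_hold.T)).T
    resid = X_hold - V @ W.T
    return float(np.sum(resid * resid))


def select_lambda(
    target: ExpressionMatrix | np.ndarray,
    W0: np.ndarray,
    grid: np.ndarray | list[float] | None = None,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[float, list[tuple[float, float]]]:
    """Two-fold selection of the transfer penalty lambda.

    Rows are shuffled by ``seed`` and split into two equal folds.  For each
    candidate lambda, the penalized factorization is fitted on one fold and
    the held-out fold is scored by project-and-reconstruct error onto the
    fitted loading; the two directions are summed.  Returns the minimizing
    lambda (ties broken toward larger lambda, i.e. more transfer) and the
    (lambda, error) table.
    """
    X = target.values if isinstance(target, ExpressionMatrix) else np.asarray(target, float)
    n0 = X.shape[0]
    if n0 < 4:
        raise ValueError("need at least 4 target rows for two-fold selection")
    if grid is None:
        grid = default_lambda_grid(n0, X.shape[1], W0)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be non-empty")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n0)
    fold_a, fold_b = perm[: n0 // 2], perm[n0 // 2 :]
    XA, XB = X[fold_a], X[fold_b]

    table: list[tuple[float, float]] = []
    for lam in grid:
        WA = fit_transfer(XA, W0, lam, max_iter=max_iter, tol=tol).W
        WB = fit_transfer(XB, W0, lam, max_iter=max_iter, tol=tol).W
        err = _projection_error(XB, WA) + _projection_error(XA, WB)
        table.append((float(lam), err))
    errors = np.array([e for _, e in table])
    # ties toward larger lambda: scan from the largest candidate down
    order = np.argsort(-grid, kind="stable")
    best = order[np.argmin(errors[order])]
    return float(grid[best]), table
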