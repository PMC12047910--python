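"""Supervised probabilistic linear dimension reduction (pLDR).

The source model is a factor-analysis model with class-conditional Gaussian
factor priors and *known* class labels:

    x_i = W0 u_i + eps_i,      eps_i ~ N(0, Lambda)   (Lambda diagonal)
    u_i | z_i = k ~ N(mu_k, Sigma_k)

Because every conditional is Gaussian, EM is fully closed form.  The E-step
is Gaussian conditioning of u_i on x_i within the known class; the M-step
updates W0, the diagonal Lambda and the per-class factor moments from the
posterior first and second moments.  The marginal likelihood

    x_i | z_i = k ~ N(W0 mu_k, W0 Sigma_k W0' + Lambda)

is monitored every iteration and is non-decreasing (standard EM guarantee).

W0 is only identified up to an invertible q×q transform; after convergence
we rotate to the standard factor-analysis representative in which
W0' Lambda^{-1} W0 is diagonal with decreasing entries, and counter-rotate
factors and class moments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .core_io import LabeledSource

LAMBDA_FLOOR = 1e-6
COV_RIDGE = 1e-6
COV_MIN_EIG = 1e-8


@dataclass
class PLDRFit:
    """Fitted Step-1 model: loading, residual variances, class moments."""

    W0: np.ndarray            # (p, q) loading matrix
    Lambda: np.ndarray        # (p,) diagonal residual variances, > 0
    class_means: np.ndarray   # (K, q) factor means mu_k
    class_covs: np.ndarray    # (K, q, q) factor covariances Sigma_k
    loglik_trace: np.ndarray  # per-iteration marginal log-likelihood
    factors: np.ndarray       # (n1, q) posterior-mean factors U
    n_iter: int = 0
    converged: bool = False

    @property
    def q(self) -> int:
        return self.W0.shape[1]


def _repair_cov(S: np.ndarray) -> np.ndarray:
    """Symmetrize and ridge-repair a covariance with tiny/negative spectrum."""
    S = 0.5 * (S + S.T)
    if np.linalg.eigvalsh(S)[0] < COV_MIN_EIG:
        warnings.warn("ridge-repairing a near-singular factor covariance",
                      stacklevel=3)
        S = S + COV_RIDGE * np.eye(S.shape[0])
    return S


def _marginal_loglik(
    X: np.ndarray,
    labels: np.ndarray,
    W: np.ndarray,
    lam: np.ndarray,
    mu: np.ndarray,
    Sig: np.ndarray,
) -> float:
    """Sum_i log N(x_i; W mu_k, W Sigma_k W' + Lambda) via Woodbury.

    Uses the matrix-determinant lemma and Woodbury identity so cost scales
    with q, not p, per class.
    """
    n, p = X.shape
    Wl = W / lam[:, None]                       # Lambda^{-1} W
    A = W.T @ Wl                                # W' Lambda^{-1} W (q×q)
    logdet_lam = float(np.sum(np.log(lam)))
    total = 0.0
    for k in range(mu.shape[0]):
        idx = np.flatnonzero(labels == k + 1)
        if idx.size == 0:
            continue
        Sk = Sig[k]
        # det(Lambda + W Sk W') = det(Lambda) det(I + Sk A)
        M = np.eye(Sk.shape[0]) + Sk @ A
        sign, logdet_M = np.linalg.slogdet(M)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                "singular marginal covariance; condition number "
                f"{np.linalg.cond(M):.3e}"
            )
        R = X[idx] - (W @ mu[k])[None, :]       # residuals (nk, p)
        # Woodbury: inv = L^-1 - L^-1 W (Sk^-1 + A)^-1 W' L^-1
        B = R @ Wl                              # (nk, q)
        inner = linalg.solve(linalg.inv(Sk) + A, B.T, assume_a="pos").T
        quad = np.einsum("ij,ij->i", R / lam[None, :], R) - np.einsum(
            "ij,ij->i", B, inner
        )
        total += float(
            -0.5 * idx.size * (p * np.log(2 * np.pi) + logdet_lam + logdet_M)
            - 0.5 * quad.sum()
        )
    return total


def _init_params(X: np.ndarray, labels: np.ndarray, q: int, K: int, seed: int):
    """SVD-based initialization: loading from top-q right singular vectors."""
    n, p = X.shape
    xbar = X.mean(axis=0)
    Xc = X - xbar
    if min(n, p) > 600:
        from sklearn.utils.extmath import randomized_svd

        U, s, Vt = randomized_svd(Xc, n_components=q, random_state=seed)
    else:
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        U, s, Vt = U[:, :q], s[:q], Vt[:q]
    W = Vt.T * (s / np.sqrt(n))
    factors = U * np.sqrt(n)                    # so Xc ≈ factors @ W.T
    resid = Xc - factors @ W.T
    lam = np.maximum(resid.var(axis=0), LAMBDA_FLOOR)
    # class moments of the initial projections; shift means so that the
    # removed global mean is absorbed approximately through W mu_k
    offset, *_ = np.linalg.lstsq(W, xbar, rcond=None)
    mu = np.zeros((K, q))
    Sig = np.zeros((K, q, q))
    for k in range(K):
        idx = labels == k + 1
        fk = factors[idx]
        mu[k] = fk.mean(axis=0) + offset
        Sig[k] = _repair_cov(np.cov(fk, rowvar=False, bias=True))
    return W, lam, mu, Sig


def fit_pldr(
    source: LabeledSource,
    q: int = 15,
    max_iter: int = 200,
    tol: float = 1e-7,
    seed: int = 0,
) -> PLDRFit:
    """Fit the supervised factor model by EM and return the learned loading.

    Parameters
    ----------
    source
        Labeled expression matrix; every class needs at least ``q + 1``
        members so class covariances are estimable.
    q
        Latent dimension (default 15).
    max_iter, tol
        EM stops when the relative marginal log-likelihood change drops
        below ``tol`` or after ``max_iter`` iterations.
    seed
        Only consumed by the randomized SVD used to initialize on large
        problems; the algorithm is otherwise deterministic.
    """
    X = source.expr.values
    labels = source.labels
    n, p = X.shape
    if q >= min(n, p):
        raise ValueError(f"q={q} must be < min(n1, p) = {min(n, p)}")
    if q < 1:
        raise ValueError("q must be positive")
    K = source.n_classes
    counts = np.bincount(labels, minlength=K + 1)[1:]
    if (counts <= q).any():
        small = np.flatnonzero(counts <= q) + 1
        raise ValueError(
            f"classes {small.tolist()} have <= q members; covariance "
            "estimation needs at least q+1 per class"
        )

    W, lam, mu, Sig = _init_params(X, labels, q, K, seed)
    trace = [_marginal_loglik(X, labels, W, lam, mu, Sig)]
    factors = np.zeros((n, q))
    converged = False

    for it in range(max_iter):
        # ----- E-step: posterior moments of u_i given x_i, class k -----
        Wl = W / lam[:, None]
        A = W.T @ Wl
        S1 = np.zeros((p, q))        # sum_i x_i E[u_i]'
        S2 = np.zeros((q, q))        # sum_i E[u_i u_i']
        class_stats = []
        for k in range(K):
            idx = np.flatnonzero(labels == k + 1)
            Sk_inv = linalg.inv(Sig[k])
            Ck = linalg.inv(A + Sk_inv)
            Ck = 0.5 * (Ck + Ck.T)
            Mk = (X[idx] @ Wl + (Sk_inv @ mu[k])[None, :]) @ Ck
            factors[idx] = Mk
            S1 += X[idx].T @ Mk
            S2 += idx.size * Ck + Mk.T @ Mk
            class_stats.append((idx, Ck, Mk))
        # ----- M-step -----
        W = linalg.solve(S2, S1.T, assume_a="pos").T
        WS2 = W @ S2
        lam = (
            np.einsum("ij,ij->j", X, X)
            - 2.0 * np.einsum("jq,jq->j", S1, W)
            + np.einsum("jq,jq->j", WS2, W)
        ) / n
        lam = np.maximum(lam, LAMBDA_FLOOR)
        for k, (idx, Ck, Mk) in enumerate(class_stats):
            mu[k] = Mk.mean(axis=0)
            D = Mk - mu[k]
            Sig[k] = _repair_cov(Ck + D.T @ D / idx.size)
        ll = _marginal_loglik(X, labels, W, lam, mu, Sig)
        trace.append(ll)
        if abs(ll - trace[-2]) < tol * (abs(trace[-2]) + 1.0):
            converged = True
            break

    W, factors, mu, Sig = _canonical_rotation(W, lam, factors, mu, Sig)
    return PLDRFit(
        W0=W,
        Lambda=lam,
        class_means=mu,
        class_covs=Sig,
        loglik_trace=np.asarray(trace),
        factors=factors,
        n_iter=len(trace) - 1,
        converged=converged,
    )


def _canonical_rotation(W, lam, factors, mu, Sig):
    """Rotate so W' Lambda^{-1} W is diagonal with decreasing entries.

    The rotation is orthogonal, so the model distribution is unchanged:
    W <- W R, u <- R' u.  Column signs are fixed so the largest-magnitude
    loading entry in each column is positive.
    """
    M = W.T @ (W / lam[:, None])
    vals, R = np.linalg.eigh(M)
    R = R[:, ::-1]                               # decreasing eigenvalues
    W = W @ R
    signs = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    W = W * signs
    R = R * signs
    factors = factors @ R
    mu = mu @ R
    Sig = np.einsum("ab,kbc,cd->kad", R.T, Sig, R)
    return W, factors, mu, Sig


def pldr_loglik(fit: PLDRFit, source: LabeledSource) -> float:
    """Marginal log-likelihood of labeled data under a fitted pLDR model."""
    if source.expr.n_genes != fit.W0.shape[0]:
        raise ValueError("gene dimension mismatch between fit and data")
    return _marginal_loglik(
        source.expr.values,
        source.labels,
        fit.W0,
        fit.Lambda,
        fit.class_means,
        fit.class_covs,
    )
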