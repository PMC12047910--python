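"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from transst.core_io import ExpressionMatrix, LabeledSource


def make_factor_model_data(
    n: int,
    p: int,
    q: int,
    K: int,
    seed: int,
    noise: float = 0.5,
    sep: float = 2.0,
    orthonormal: bool = True,
):
    """Draw labeled data from the supervised factor model itself.

    Returns (LabeledSource, true loading W, true class means).  Class means
    are ``sep``-scaled coordinate directions, class covariances identity.
    """
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((p, q))
    if orthonormal:
        W, _ = np.linalg.qr(W)
    z = rng.integers(1, K + 1, size=n)
    mu = np.zeros((K, q))
    for k in range(K):
        mu[k, k % q] = sep * (1 if k % 2 == 0 else -1)
    U = mu[z - 1] + rng.standard_normal((n, q))
    X = U @ W.T + noise * rng.standard_normal((n, p))
    src = LabeledSource(
        ExpressionMatrix(X, [f"r{i}" for i in range(n)], [f"g{j}" for j in range(p)]),
        z,
    )
    return src, W, mu


def hard_em_gmm(V: np.ndarray, init_labels: np.ndarray, K: int, max_iter: int = 50):
    """Independent classification-EM GMM oracle (hard assignments).

    Alternates argmax-density assignment with moment updates, mirroring no
    code from the package beyond numpy primitives.
    """
    labels = init_labels.copy()
    n, q = V.shape
    for _ in range(max_iter):
        means = np.zeros((K, q))
        covs = np.zeros((K, q, q))
        for k in range(K):
            Vk = V[labels == k + 1]
            if len(Vk) == 0:   # oracle only used on instances without empties
                raise RuntimeError("empty cluster in oracle")
            means[k] = Vk.mean(axis=0)
            C = np.cov(Vk, rowvar=False, bias=True).reshape(q, q)
            C = 0.5 * (C + C.T)
            if len(Vk) <= q or np.linalg.eigvalsh(C)[0] < 1e-8:
                C = C + 1e-6 * np.eye(q)
            covs[k] = C
        logd = np.empty((n, K))
        for k in range(K):
            sign, ld = np.linalg.slogdet(covs[k])
            D = V - means[k]
            sol = np.linalg.solve(covs[k], D.T).T
            logd[:, k] = -0.5 * (np.einsum("ij,ij->i", D, sol) + ld + q * np.log(2 * np.pi))
        new = np.argmax(logd, axis=1) + 1
        if np.array_equal(new, labels):
            break
        labels = new
    return labels


def lattice_coords(height: int, width: int) -> np.ndarray:
    ii, jj = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    return np.column_stack([jj.ravel(), ii.ravel()]).astype(float)


@pytest.fixture
def small_sim():
    """A small paired source/target benchmark used across modules."""
    from transst.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(height=12, width=12, n1=300, p=60, q=5, K=3, seed=11)
    source, target = simulate_dataset(cfg)
    return cfg, source, target
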