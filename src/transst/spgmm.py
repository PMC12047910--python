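"""Spatial Gaussian mixture clustering with a Potts label prior (spGMM).

Target factors v_i are modeled as class-conditional Gaussians,
v_i | z_i = k ~ N(mu_k, Sigma_k), while the label field z carries a Potts
Markov-random-field prior over a k-nearest-neighbor spatial graph:

    f(z) ∝ exp{ -1/2 sum_i sum_{i' in N_i} beta (1 - I{z_i = z_i'}) }.

Because the graph is symmetric every unordered pair appears twice in the
double sum, so the 1/2 cancels in each site's conditional and the ICM score
for assigning class k to spot i is

    log N(v_i; mu_k, Sigma_k) - beta * #{i' in N_i : z_i' != k}.

Inference is ICM-EM: iterated-conditional-modes label sweeps alternate with
moment updates of (mu_k, Sigma_k) from the hard assignments.  beta is chosen
on [0, 1] by a grid line search maximizing the conditional pseudo-likelihood
(the Potts normalizing constant is intractable); beta = 0 recovers a plain
hard-assignment GMM.  The number of clusters K, when unknown, is chosen by a
BIC-type penalty on the best-beta pseudo-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

COV_RIDGE = 1e-6
COV_MIN_EIG = 1e-8
DEFAULT_BETA_GRID = np.round(np.linspace(0.0, 1.0, 11), 10)


@dataclass
class SpatialGraph:
    """Symmetrized k-nearest-neighbor graph over spot coordinates."""

    neighbors: list[np.ndarray]
    k: int
    symmetric: bool = True

    @property
    def n_spots(self) -> int:
        return len(self.neighbors)

    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])


@dataclass
class SpGMMFit:
    labels: np.ndarray              # (n0,) in 1..K
    K: int
    beta: float
    means: np.ndarray               # (K, q)
    covs: np.ndarray                # (K, q, q)
    responsibilities: np.ndarray    # (n0, K) row-stochastic
    pseudo_loglik: float
    beta_table: list[tuple[float, float]] = field(default_factory=list)
    criterion_table: list[tuple[int, float]] | None = None
    n_iter: int = 0


def build_knn_graph(coords, k: int = 5) -> SpatialGraph:
    """Euclidean k-nearest-neighbor graph, self excluded, union-symmetrized.

    Distance ties are broken deterministically toward the lower row index.
    The default k = 5 neighbors is the working choice for all experiments.
    """
    from .core_io import SpatialCoords

    if isinstance(coords, SpatialCoords):
        xy = coords.coords
    else:
        xy = np.asarray(coords, dtype=float)
    n = xy.shape[0]
    if k < 1:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of spots {n}")

    sq = np.einsum("ij,ij->i", xy, xy)
    knn = np.empty((n, k), dtype=np.int64)
    chunk = max(1, int(2e7) // max(n, 1))
    idx_all = np.arange(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (xy[start:stop] @ xy.T)
        np.maximum(d2, 0.0, out=d2)
        rows = np.arange(start, stop)
        d2[rows - start, rows] = np.inf          # exclude self
        # primary key distance, secondary key index (lexsort: last key primary)
        order = np.lexsort((np.broadcast_to(idx_all, d2.shape), d2), axis=1)
        knn[start:stop] = order[:, :k]

    sets: list[set[int]] = [set(row) for row in knn]
    for i, row in enumerate(knn):
        for j in row:
            sets[int(j)].add(i)
    neighbors = [np.array(sorted(s), dtype=np.int64) for s in sets]
    return SpatialGraph(neighbors=neighbors, k=k, symmetric=True)


def potts_neighbor_disagreement(
    labels: np.ndarray, graph: SpatialGraph, i: int, k: int
) -> int:
    """Number of neighbors of spot ``i`` whose label differs from class ``k``.

    The 1/2 in the joint Potts density cancels for conditional scores on a
    symmetric graph (each pair is counted twice), so conditionals use this
    unhalved count.
    """
    nb = graph.neighbors[i]
    return int(np.count_nonzero(labels[nb] != k))


def _gauss_logdens(V: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """(n, K) matrix of log N(v_i; mu_k, Sigma_k)."""
    n, q = V.shape
    K = means.shape[0]
    out = np.empty((n, K))
    for k in range(K):
        L = np.linalg.cholesky(covs[k])
        D = np.linalg.solve(L, (V - means[k]).T)
        out[:, k] = (
            -0.5 * np.einsum("ji,ji->i", D, D)
            - np.sum(np.log(np.diag(L)))
            - 0.5 * q * np.log(2.0 * np.pi)
        )
    return out


def _moments_from_labels(
    V: np.ndarray, labels: np.ndarray, K: int
) -> tuple[np.ndarray, np.ndarray]:
    q = V.shape[1]
    means = np.zeros((K, q))
    covs = np.zeros((K, q, q))
    for k in range(K):
        Vk = V[labels == k + 1]
        if len(Vk) == 0:
            raise _EmptyCluster(k)
        means[k] = Vk.mean(axis=0)
        C = np.cov(Vk, rowvar=False, bias=True).reshape(q, q)
        C = 0.5 * (C + C.T)
        if len(Vk) <= q or np.linalg.eigvalsh(C)[0] < COV_MIN_EIG:
            C = C + COV_RIDGE * np.eye(q)
        covs[k] = C
    return means, covs


class _EmptyCluster(Exception):
    def __init__(self, k: int):
        self.k = k


def _agree_counts(labels: np.ndarray, neighbors: list[np.ndarray], K: int) -> np.ndarray:
    """(n, K) counts of neighbors of each spot currently labeled each class."""
    n = len(labels)
    out = np.zeros((n, K), dtype=np.int64)
    for i, nb in enumerate(neighbors):
        out[i] = np.bincount(labels[nb] - 1, minlength=K)
    return out


def _icm_sweeps(
    labels: np.ndarray,
    logdens: np.ndarray,
    neighbors: list[np.ndarray],
    beta: float,
    K: int,
    max_sweeps: int = 10,
) -> np.ndarray:
    """Cycle spots, setting each label to its conditional mode, until stable.

    Maximizing log N + beta*#agreements equals the stated score
    log N - beta*#disagreements up to a per-spot constant.  Each update can
    only increase the joint (likelihood + Potts) objective.
    """
    labels = labels.copy()
    n = len(labels)
    if beta == 0.0:
        labels = np.argmax(logdens, axis=1) + 1
        return labels
    for _ in range(max_sweeps):
        changed = False
        for i in range(n):
            nb = neighbors[i]
            score = logdens[i] + beta * np.bincount(labels[nb] - 1, minlength=K)
            new = int(np.argmax(score)) + 1
            if new != labels[i]:
                labels[i] = new
                changed = True
        if not changed:
            break
    return labels


def joint_objective(
    V: np.ndarray,
    labels: np.ndarray,
    graph: SpatialGraph,
    means: np.ndarray,
    covs: np.ndarray,
    beta: float,
) -> float:
    """Hard-assignment log-posterior (up to the Potts normalizing constant)."""
    logdens = _gauss_logdens(V, means, covs)
    ll = float(logdens[np.arange(len(labels)), labels - 1].sum())
    disagree = sum(
        np.count_nonzero(labels[nb] != labels[i])
        for i, nb in enumerate(graph.neighbors)
    )
    return ll - 0.5 * beta * disagree


def _pseudo_loglik(
    logdens: np.ndarray, labels: np.ndarray, neighbors: list[np.ndarray],
    beta: float, K: int,
) -> float:
    """Conditional pseudo-likelihood sum_i log of the mixture of per-class
    Gaussian densities weighted by the Potts conditional prior at site i."""
    agree = _agree_counts(labels, neighbors, K)
    deg = np.array([len(nb) for nb in neighbors])[:, None]
    prior_score = -beta * (deg - agree)          # -beta * disagreements
    num = logsumexp(logdens + prior_score, axis=1)
    den = logsumexp(prior_score, axis=1)
    return float(np.sum(num - den))


def _fit_one_beta(
    V: np.ndarray,
    graph: SpatialGraph,
    K: int,
    beta: float,
    init_labels: np.ndarray,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, int]:
    labels = init_labels.copy()
    neighbors = graph.neighbors
    means = covs = None
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        labels = _repair_empty(V, labels, K)
        means, covs = _moments_from_labels(V, labels, K)
        logdens = _gauss_logdens(V, means, covs)
        new_labels = _icm_sweeps(labels, logdens, neighbors, beta, K)
        if np.array_equal(new_labels, labels) and it > 0:
            labels = new_labels
            break
        labels = new_labels
    labels = _repair_empty(V, labels, K)
    means, covs = _moments_from_labels(V, labels, K)
    logdens = _gauss_logdens(V, means, covs)
    agree = _agree_counts(labels, neighbors, K)
    deg = np.array([len(nb) for nb in neighbors])[:, None]
    scores = logdens - beta * (deg - agree)
    resp = np.exp(scores - logsumexp(scores, axis=1, keepdims=True))
    pll = _pseudo_loglik(logdens, labels, neighbors, beta, K)
    return labels, means, covs, resp, pll, n_iter


def _repair_empty(V: np.ndarray, labels: np.ndarray, K: int) -> np.ndarray:
    """Re-seed each empty component at the currently worst-explained point.

    The worst-explained point is the one with the lowest best per-class log
    density under moments computed from the non-empty components.
    """
    labels = labels.copy()
    q = V.shape[1]
    for _ in range(K):
        empty = [k for k in range(K) if not np.any(labels == k + 1)]
        if not empty:
            break
        means = np.zeros((K, q))
        covs = np.tile(np.eye(q), (K, 1, 1))
        for k in range(K):
            Vk = V[labels == k + 1]
            if len(Vk) == 0:
                continue
            means[k] = Vk.mean(axis=0)
            C = np.cov(Vk, rowvar=False, bias=True).reshape(q, q)
            covs[k] = 0.5 * (C + C.T) + COV_RIDGE * np.eye(q)
        logdens = _gauss_logdens(V, means, covs)
        warnings.warn(f"re-seeding empty cluster {empty[0] + 1}", stacklevel=3)
        worst = int(np.argmin(logdens.max(axis=1)))
        labels[worst] = empty[0] + 1
    return labels


def initial_labels(V: np.ndarray, K: int, seed: int = 0) -> np.ndarray:
    """Shared k-means++ initialization (10 restarts, best inertia)."""
    if K == 1:
        return np.ones(len(V), dtype=int)
    km = KMeans(n_clusters=K, init="k-means++", n_init=10, random_state=seed)
    return km.fit_predict(V).astype(int) + 1


def fit_spgmm(
    V: np.ndarray,
    graph: SpatialGraph,
    K: int,
    beta_grid=None,
    max_iter: int = 50,
    seed: int = 0,
    init: np.ndarray | None = None,
) -> SpGMMFit:
    """Fit the spatial GMM for each beta on the grid; keep the best.

    All betas share one k-means++ initialization so the line search is a
    paired comparison; each beta is scored by its conditional
    pseudo-likelihood and the best-scoring fit is returned (ties toward
    smaller beta, the less-regularized model).
    """
    V = np.asarray(V, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    if K < 1:
        raise ValueError("K must be at least 1")
    if graph.n_spots != len(V):
        raise ValueError("graph size does not match factor matrix")
    if beta_grid is None:
        beta_grid = DEFAULT_BETA_GRID
    beta_grid = [float(b) for b in beta_grid]
    if any(b < 0 or b > 1 for b in beta_grid):
        raise ValueError("beta grid must lie in [0, 1]")

    labels0 = init.copy() if init is not None else initial_labels(V, K, seed)
    best = None
    table = []
    for beta in beta_grid:
        labels, means, covs, resp, pll, n_iter = _fit_one_beta(
            V, graph, K, beta, labels0, max_iter
        )
        table.append((beta, pll))
        if best is None or pll > best.pseudo_loglik:
            best = SpGMMFit(
                labels=labels, K=K, beta=beta, means=means, covs=covs,
                responsibilities=resp, pseudo_loglik=pll, n_iter=n_iter,
            )
    best.beta_table = table
    return best


def select_K(
    V: np.ndarray,
    graph: SpatialGraph,
    K_range,
    beta_grid=None,
    seed: int = 0,
    max_iter: int = 50,
    criterion=None,
) -> tuple[int, list[tuple[int, float]], dict[int, SpGMMFit]]:
    """Choose K by a BIC-type criterion on the best-beta pseudo-likelihood.

    criterion(K, pll, n0, q) defaults to
    ``-2*pll + log(n0) * (K*q + K*q*(q+1)/2)`` — the mixture's mean and
    covariance parameter count.  Returns (K_hat, criterion table, fits);
    ties break toward smaller K, failed fits are skipped with a warning.
    """
    V = np.asarray(V, dtype=float)
    K_range = sorted(set(int(K) for K in K_range))
    if not K_range or min(K_range) < 1:
        raise ValueError("K_range must be non-empty with min >= 1")
    n0, q = V.shape
    if criterion is None:
        def criterion(K, pll, n0, q):
            d_K = K * q + K * q * (q + 1) // 2
            return -2.0 * pll + np.log(n0) * d_K

    table: list[tuple[int, float]] = []
    fits: dict[int, SpGMMFit] = {}
    for K in K_range:
        try:
            fit = fit_spgmm(V, graph, K, beta_grid, max_iter=max_iter, seed=seed)
        except Exception as exc:   # noqa: BLE001 - any single-K failure skips K
            warnings.warn(f"fit with K={K} failed ({exc}); skipping", stacklevel=2)
            continue
        fits[K] = fit
        table.append((K, float(criterion(K, fit.pseudo_loglik, n0, q))))
    if not table:
        raise RuntimeError("every candidate K failed to fit")
    crits = np.array([c for _, c in table])
    K_hat = table[int(np.argmin(crits))][0]     # first min -> smallest K
    return K_hat, table, fits
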