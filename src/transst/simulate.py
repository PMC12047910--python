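"""Synthetic benchmark generator: Potts labels → Gaussian factors → genes.

The design mirrors the standard spatial-transcriptomics simulation:

1. Target spot labels are drawn from a K-state Potts model on a
   height × width rook-adjacency lattice at interaction strength
   ``beta_true`` (Gibbs sampling); source labels are i.i.d. uniform since
   the source carries no spatial structure.
2. Each spot's latent factor is cluster-conditionally Gaussian,
   u | z = k ~ N(mu_k, I_q), with mu_k = effect_size × fixed unit
   directions (±e_j in cycling coordinates).
3. Factors map to gene space through a shared p × q loading matrix with
   orthonormal columns (QR of a seeded Gaussian matrix); both matrices then
   receive i.i.d. residual noise ``sigma × N(0, 1)``, the factor model's
   measurement noise.
4. Marker-gene structure: for each cluster k, ``effect_size`` is added to
   the designated marker columns of that cluster's rows.  The default map
   gives clusters 1..K-1 one unique marker gene each and the last cluster a
   block of seven, so that (for K = 4) genes 1, 2, 3 and 4–10 uniquely
   determine clusters 1–4.
5. The target additionally receives elementwise noise
   ``noise_e × N(0, 1)`` on top of the shared residual noise, emulating a
   lower-quality target study; coordinates are the lattice positions.

Identical configurations (including seed) produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ExpressionMatrix, LabeledSource, SpatialCoords

#: Benchmark scenario presets (n0 = lattice size, n1 = source size), p = 200.
SCENARIOS = {
    "s1": dict(height=100, width=100, n1=2500, p=200),
    "s2": dict(height=100, width=200, n1=2500, p=200),
    "s3": dict(height=100, width=100, n1=5000, p=200),
    "s4": dict(height=100, width=100, n1=10000, p=200),
}


def default_marker_map(K: int, p: int) -> dict[int, tuple[int, ...]]:
    """Clusters 1..K-1 get one unique marker gene; cluster K gets a 7-block.

    For K = 4 this is genes {0}, {1}, {2}, {3..9} (0-based), i.e. genes
    1, 2, 3 and 4–10 uniquely determine clusters 1–4.
    """
    mm = {k: (k - 1,) for k in range(1, K)}
    mm[K] = tuple(range(K - 1, min(K + 6, p)))
    return mm


@dataclass
class SimConfig:
    """Benchmark configuration; all knobs of the generative design."""

    height: int = 30
    width: int = 30
    n1: int = 1000
    p: int = 200
    q: int = 15
    K: int = 4
    beta_true: float = 1.0
    sigma: float = 1.0
    noise_e: float = 0.0
    effect_size: float = 1.5
    marker_map: dict[int, tuple[int, ...]] | None = None
    seed: int = 0
    potts_sweeps: int = 60

    def __post_init__(self) -> None:
        if self.K < 2 or self.q < 1:
            raise ValueError("need K >= 2 and q >= 1")
        if self.beta_true < 0 or self.noise_e < 0 or self.sigma < 0:
            raise ValueError("beta_true, sigma and noise_e must be nonnegative")
        if self.marker_map is None:
            self.marker_map = default_marker_map(self.K, self.p)
        used: set[int] = set()
        for k, genes in self.marker_map.items():
            if not (1 <= k <= self.K):
                raise ValueError(f"marker_map key {k} outside 1..K")
            for g in genes:
                if not (0 <= g < self.p):
                    raise ValueError(f"marker gene index {g} outside 0..p-1")
                if g in used:
                    raise ValueError(f"marker gene {g} assigned to two clusters")
                used.add(g)

    @property
    def n0(self) -> int:
        return self.height * self.width


@dataclass
class TargetData:
    """Simulated target: expression, lattice coordinates, true labels."""

    expr: ExpressionMatrix
    coords: SpatialCoords
    labels: np.ndarray


def _checkerboard_masks(height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    ii, jj = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    even = (ii + jj) % 2 == 0
    return even, ~even


def _neighbor_agree(labels: np.ndarray, K: int) -> np.ndarray:
    """(..., h, w, K) counts of rook neighbors agreeing with each class.

    Works on a batch of lattices (leading chain axis) without wraparound.
    """
    pad = np.pad(labels, [(0, 0)] * (labels.ndim - 2) + [(1, 1), (1, 1)],
                 constant_values=-1)
    up = pad[..., :-2, 1:-1]
    down = pad[..., 2:, 1:-1]
    left = pad[..., 1:-1, :-2]
    right = pad[..., 1:-1, 2:]
    agree = np.zeros(labels.shape + (K,), dtype=np.int64)
    for k in range(K):
        agree[..., k] = sum((nb == k).astype(np.int64)
                            for nb in (up, down, left, right))
    return agree


def sample_potts_ensemble(
    height: int, width: int, K: int, beta: float,
    sweeps: int = 60, seed: int = 0, n_chains: int = 1,
) -> np.ndarray:
    """Sample ``n_chains`` independent Potts lattices by checkerboard Gibbs.

    Full conditionals are P(z_i = k | rest) ∝ exp(-beta · #{neighbors ≠ k})
    on the rook lattice.  The rook lattice is bipartite, so same-color sites
    are conditionally independent and can be updated as one exact Gibbs
    block; sampling uses the Gumbel-max trick for vectorization.  Chains
    start from i.i.d. uniform states.  Labels are 0-based internally here;
    callers wanting 1..K add 1.
    """
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, K, size=(n_chains, height, width))
    even, odd = _checkerboard_masks(height, width)
    for _ in range(sweeps):
        for mask in (even, odd):
            agree = _neighbor_agree(labels, K)
            gumbel = rng.gumbel(size=(n_chains, height, width, K))
            draw = np.argmax(beta * agree + gumbel, axis=-1)
            labels[:, mask] = draw[:, mask]
    return labels


def sample_potts(
    height: int, width: int, K: int, beta: float,
    sweeps: int = 60, seed: int = 0,
) -> np.ndarray:
    """Single height × width Potts lattice with labels in 1..K."""
    return (
        sample_potts_ensemble(height, width, K, beta, sweeps, seed, n_chains=1)[0]
        + 1
    )


def cluster_directions(K: int, q: int) -> np.ndarray:
    """Deterministic unit directions ±e_j for the K cluster factor means."""
    dirs = np.zeros((K, q))
    extra_rng = np.random.default_rng(12345)    # only reached when K > 2q
    for k in range(K):
        j, sign = divmod(k, 2)
        if j < q:
            dirs[k, j] = 1.0 if sign == 0 else -1.0
        else:
            v = extra_rng.standard_normal(q)
            dirs[k] = v / np.linalg.norm(v)
    return dirs


def _orthonormal_loading(p: int, q: int, rng: np.random.Generator) -> np.ndarray:
    Q, R = np.linalg.qr(rng.standard_normal((p, q)))
    return Q * np.sign(np.diag(R))              # deterministic sign convention


def simulate_dataset(cfg: SimConfig) -> tuple[LabeledSource, TargetData]:
    """Generate one paired (source, target) benchmark dataset.

    Returns a labeled, non-spatial source and a spatial target whose true
    lattice labels are carried alongside the expression and coordinates.
    """
    ss = np.random.SeedSequence([int(cfg.seed), 777])
    s_potts, s_src, s_factors, s_loading, s_noise = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    ]

    z_tgt = sample_potts(
        cfg.height, cfg.width, cfg.K, cfg.beta_true, cfg.potts_sweeps, s_potts
    ).ravel()
    rng_src = np.random.default_rng(s_src)
    z_src = rng_src.integers(1, cfg.K + 1, size=cfg.n1)

    mu = cfg.effect_size * cluster_directions(cfg.K, cfg.q)
    rng_f = np.random.default_rng(s_factors)
    U = mu[z_src - 1] + rng_f.standard_normal((cfg.n1, cfg.q))
    V = mu[z_tgt - 1] + rng_f.standard_normal((cfg.n0, cfg.q))

    W = _orthonormal_loading(cfg.p, cfg.q, np.random.default_rng(s_loading))

    X_src = U @ W.T
    X_tgt = V @ W.T
    for k, genes in cfg.marker_map.items():
        X_src[np.ix_(z_src == k, list(genes))] += cfg.effect_size
        X_tgt[np.ix_(z_tgt == k, list(genes))] += cfg.effect_size
    rng_n = np.random.default_rng(s_noise)
    if cfg.sigma > 0:
        X_src = X_src + cfg.sigma * rng_n.standard_normal(X_src.shape)
        X_tgt = X_tgt + cfg.sigma * rng_n.standard_normal(X_tgt.shape)
    if cfg.noise_e > 0:
        X_tgt = X_tgt + cfg.noise_e * rng_n.standard_normal(X_tgt.shape)

    gene_ids = [f"gene{j + 1}" for j in range(cfg.p)]
    source = LabeledSource(
        ExpressionMatrix(
            X_src, [f"src{i}" for i in range(cfg.n1)], gene_ids
        ),
        z_src,
    )
    ii, jj = np.meshgrid(
        np.arange(cfg.height), np.arange(cfg.width), indexing="ij"
    )
    coords = SpatialCoords(
        np.column_stack([jj.ravel(), ii.ravel()]).astype(float),
        [f"tgt{i}" for i in range(cfg.n0)],
    )
    target = TargetData(
        expr=ExpressionMatrix(
            X_tgt, [f"tgt{i}" for i in range(cfg.n0)], gene_ids
        ),
        coords=coords,
        labels=z_tgt,
    )
    return source, target


def scenario_config(name: str, **overrides) -> SimConfig:
    """Named benchmark scenario (s1–s4) as a SimConfig, overridable."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    return SimConfig(**{**SCENARIOS[name], **overrides})
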