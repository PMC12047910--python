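# Methods

This note records the model assumptions, estimation choices, defaults and
known limitations of the `transst` implementation. Notation follows the
README: source `Xsrc ∈ ℝ^{n1×p}` with labels `z`, target `Xtgt ∈ ℝ^{n0×p}`
with 2-D coordinates, latent dimension `q`.

## Step 1 — supervised factor model (pLDR)

**Model.** `x_i = W0 u_i + ε_i`, `ε_i ~ N(0, Λ)` with Λ diagonal, and
`u_i | z_i = k ~ N(μ_k, Σ_k)` with the class label known. Marginally,
`x_i | z_i = k ~ N(W0 μ_k, W0 Σ_k W0ᵀ + Λ)`.

**Estimation.** The model is fully conjugate, so EM is closed form. The
E-step is Gaussian conditioning within the known class: posterior
covariance `C_k = (W0ᵀΛ⁻¹W0 + Σ_k⁻¹)⁻¹` shared across spots of class k,
posterior mean `m_i = C_k (W0ᵀΛ⁻¹x_i + Σ_k⁻¹μ_k)`. The M-step updates W0
from the usual cross-moment system, Λ from per-gene expected residuals,
and (μ_k, Σ_k) from class-wise posterior moments. The marginal
log-likelihood is evaluated every iteration via the Woodbury identity and
matrix-determinant lemma (cost scales with q, not p) and is monotone up to
the degeneracy guards below; the stopping rule is relative change < 1e-7
(default) or 200 iterations.

**Identifiability.** W0 is only identified up to an invertible q×q
transform. After convergence we rotate to the factor-analysis canonical
form in which `W0ᵀΛ⁻¹W0` is diagonal with decreasing entries, fix column
signs so each column's largest-magnitude loading is positive, and
counter-rotate factors and class moments. Two runs from different seeds
agree in span(W0) on well-conditioned data; the reported W0 is a
reproducible representative.

**Initialization.** SVD of the centered source: W0 from the top-q right
singular vectors scaled by `s/√n`, Λ from the residual variances, class
moments from the initial projections. `seed` only matters when the
randomized SVD path is taken (min(n, p) > 600).

**Guards.** Λ entries floored at 1e-6; Σ_k ridge-repaired with 1e-6·I when
the smallest eigenvalue drops below 1e-8. When a guard binds, strict EM
monotonicity can be violated at the guard's magnitude; the trace tolerance
in the tests (1e-8 relative) reflects this.

## Step 2 — adaptive transfer

**Objective.** `Σ_i ‖xtgt_i − W v_i‖² + λ‖W − Ŵ0‖²_F`, biconvex in (V, W).
Alternating exact minimization from `W = Ŵ0`:
`V = X W (WᵀW)⁻¹`, then `W = (XᵀV + λŴ0)(VᵀV + λI)⁻¹`. Each half-step is
the exact block minimizer, so the objective is non-increasing; convergence
at relative change < 1e-6 or 200 iterations. Near-singular Gram matrices
receive a 1e-8 ridge with a warning. At λ = 0 the stationary points are
rank-q fits and the converged objective equals the trailing
squared-singular-value sum (checked against an SVD oracle in the tests);
as λ → ∞, W → Ŵ0 and V becomes the least-squares projection onto
span(Ŵ0).

**λ selection.** Target rows are shuffled by the given seed and split into
two equal folds. "Reconstructing" held-out rows with a fold's fitted
loading is interpreted as least-squares projection onto its span — the
held-out rows have no fitted factors, so projection is the only label-free
reconstruction. The cv error for a candidate λ is the sum of the two
directions' held-out squared residuals; ties break toward larger λ (more
transfer). The default grid is `{0, 0.01, 0.1, 1, 10, 100} ×
n0·p/(‖Ŵ0‖²_F + 1)`; the multiplier makes the penalty commensurate with
the data term across problem sizes. After selection the final fit is
refitted on all rows at λ*.

**Factor parameterization for clustering.** `fit_transfer` returns the
(V, W) that minimize the objective; V is near-whitened because W carries
the scale. The pipeline hands clustering the variance-carrying coordinates
`F = Xtgt·Q` with `Q = orth(span(W))` (identically `V·Rᵀ` for `W = QR` —
the same factorization, reparameterized). Reason: the Gaussian mixture
likelihood is affine-equivariant but the shared k-means initialization is
not, and whitened factors weight pure-noise dimensions equally with
discriminative ones, which measurably degrades the initialization.

## Step 3 — spatial GMM with Potts prior

**Model.** `v_i | z_i = k ~ N(μ_k, Σ_k)`;
`f(z) ∝ exp{−½ Σ_i Σ_{i'∈N_i} β(1 − I{z_i = z_i'})}`. The neighborhoods
are Euclidean k-nearest neighbors of the spot coordinates (default k = 5),
self excluded, distance ties broken toward the lower row index,
union-symmetrized. On a symmetric graph each unordered pair appears twice
in the double sum, so the ½ cancels in every site conditional and the ICM
score for class k at spot i is
`log N(v_i; μ_k, Σ_k) − β·#{i'∈N_i : z_{i'} ≠ k}`.

**Inference.** ICM-EM: sequential label sweeps to the conditional mode
(at most 10 sweeps per outer iteration; each single-site move cannot
decrease the joint objective), then moment updates of (μ_k, Σ_k) from the
hard assignments; outer loop to label stability or 50 iterations. Soft
responsibilities are recorded as the softmax of the same per-class scores
but are not used for updates. Empty components are re-seeded at the
currently worst-explained point, with a warning. Covariances get a 1e-6·I
ridge when near-singular or when a component has ≤ q members.

**β line search.** All β candidates (default grid 0, 0.1, …, 1.0) share
one k-means++ initialization (10 restarts, best inertia, seeded) so the
comparison is paired. Each fit is scored by the conditional
pseudo-likelihood
`Σ_i log [ Σ_k N(v_i; μ_k, Σ_k) e^{−β d_ik} / Σ_k e^{−β d_ik} ]` with
`d_ik` the neighbor-disagreement count — the Potts normalizing constant is
intractable, and the pseudo-likelihood is the standard surrogate. β = 0
reduces the whole procedure exactly to a hard-EM (classification) GMM,
which the tests verify against an independent implementation.

**K selection.** For each K in the range, fit at all β and score
`−2·(best-β pseudo-likelihood) + log(n0)·d_K` with
`d_K = K·q + K·q(q+1)/2` (component means plus covariances); smallest
criterion wins, ties toward smaller K. The criterion function is an
argument of `select_K`, so alternative penalties can be plugged in.
*Limitation:* with full covariances the penalty grows like K·q²/2; at
q = 15 and n0 ≈ 10³ it dominates the pseudo-likelihood gain of splitting
*overlapping* clusters, and K is under-selected on such designs. K
recovery is reliable on separated clusters (the regime the selection
experiments validate); for overlapping data at large q, either supply K,
reduce q, or pass a milder criterion.

## Preprocessing and gene-space handling

Raw counts are library-size normalized to the median row total, log1p
transformed, subset to the `n_hvg` (default 2000) highest-variance genes on
the log scale (ties broken by original column order after quantizing
variances to 12 relative digits, which keeps the step idempotent), then
per-gene centered and unit-scaled. Rows with zero total count are an error;
variance-zero genes are dropped with a warning. Multiple source samples are
each subset to the target's genes (absent genes zero-filled and reported,
so the loading keeps full target-gene dimension), normalized independently,
and concatenated, with label codes unified by string identity. Zero-filled
columns are centered but not scaled inside source combination; the joint
source/target drop of zero-variance genes happens in the pipeline's
harmonization step, where both matrices are available. Source and target
are deliberately normalized separately, then aligned — nothing in the
method requires joint scaling, and separate normalization keeps sources
exchangeable.

## Synthetic benchmark

The generator emulates the lattice benchmark design: target labels from a
K-state Potts model on a rook-adjacency lattice (checkerboard-block Gibbs —
the rook lattice is bipartite, so same-color sites are conditionally
independent and the block update is exact Gibbs; chains start uniform,
default 60 sweeps); source labels i.i.d. uniform (the source has no spatial
structure and Step 1 never sees coordinates); factors
`u | z = k ~ N(effect_size·dir_k, I_q)` with `dir_k` cycling signed
coordinate directions; a shared orthonormal p×q loading from a seeded
Gaussian QR; marker structure added in gene space (cluster k's rows get
`effect_size` added to its marker columns — the construction that makes
single genes literally determine clusters; defaults give clusters 1..K−1
one unique marker and cluster K a block of seven, i.e. genes 1, 2, 3, 4–10
for K = 4); i.i.d. residual noise `sigma·N(0,1)` on both matrices (default
sigma = 1, the factor model's measurement noise — without it the source is
exactly low-rank and supervised loading estimation degenerates to source
PCA); and additional target-only noise `noise_e·N(0,1)` emulating a
lower-quality target study. Scenario presets s1–s4 fix
(n0, n1) ∈ {(10000, 2500), (20000, 2500), (10000, 5000), (10000, 10000)}
at p = 200.

Defaults (30×30 lattice, n1 = 1000, p = 200, q = 15, K = 4, β_true = 1,
effect_size = 1.5) were chosen to put the benchmark in the informative
middle regime: clusters separable but not trivially so (pairwise factor
mean separations of 2.1–3 within-cluster standard deviations), so that both
the spatial prior and the transferred loading have measurable headroom, and
performance degrades as `noise_e` grows. Everything is exposed in
`SimConfig`; identical configurations produce bit-identical data.

**What the simulator does not emulate:** count-level noise
(negative-binomial overdispersion, dropout), batch effects between source
samples, platform differences, spatially varying cell density, or doublets.
Passing benchmarks here demonstrates correctness of the estimation
machinery under the stated generative model, not robustness to real-data
artifacts — real use should treat preprocessing and q/K choices as
data-analysis decisions.

## Evaluation utilities

The adjusted Rand index is computed from the contingency table with exact
integer arithmetic (arbitrary-precision binomial sums; only the final
division is floating point), returning 1.0 by convention when both margins
are degenerate. Marker ranking is one-vs-rest two-sided Wilcoxon rank-sum
per cluster and gene (exact null for small groups without ties, normal
approximation otherwise), Benjamini–Hochberg adjustment within cluster,
rank by ascending adjusted p then descending |lfc|; the log fold-change is
the difference of group means, appropriate for log-scale or standardized
input. Constant genes get p = 1 with a warning.

## Reproducibility

Every stochastic component takes an explicit seed. The pipeline derives
per-stage seeds from the top-level seed through `numpy.random.SeedSequence`
(all below 2³¹), so stages can be re-run in isolation; runs with identical
configurations produce byte-identical label files. Benchmark experiment
sizes in the tests and the reproduction script (10–20 replicates, lattices
of 10×10 to 30×30, n1 up to 5000) are desk-scale choices that keep the full
suite runnable in a couple of minutes while leaving each comparison's
direction stable across seeds.
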