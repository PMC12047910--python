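"""Clustering evaluation and one-vs-rest marker-gene ranking.

The adjusted Rand index is computed with exact integer arithmetic on the
contingency table (Python's arbitrary-precision ints via math.comb), which
stays exact for partitions of up to ~10^5 items where naive floating-point
binomial sums would lose precision.  Marker genes are ranked per cluster by
a two-sided Wilcoxon rank-sum test of the cluster's spots against all
others with Benjamini–Hochberg adjustment within the cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two partitions.

    Standard permutation-model ARI from the contingency table:
    ``(index - expected) / (max - expected)`` with all binomial sums done
    in exact integer arithmetic; only the final division is floating point.
    Returns 1.0 for identical partitions and 0 in expectation under
    independent random partitions.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 elements")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = pd.crosstab(ai, bi).to_numpy()

    sum_ij = sum(comb(int(nij), 2) for nij in table.ravel())
    sum_a = sum(comb(int(x), 2) for x in table.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in table.sum(axis=0))
    total = comb(n, 2)
    # work over the common denominator `total` to stay in integers
    expected_num = sum_a * sum_b                    # expected * total
    max_num = (sum_a + sum_b) * total               # 2 * max * total
    index_num = sum_ij * total
    denom = max_num - 2 * expected_num
    if denom == 0:
        return 1.0                                  # both partitions trivial
    return float(2 * (index_num - expected_num) / denom)


def k_error(K_hat: int, K_true: int) -> int:
    """Absolute error |K_hat − K_true| of the estimated cluster count."""
    if K_hat < 1 or K_true < 1:
        raise ValueError("cluster counts must be >= 1")
    return abs(int(K_hat) - int(K_true))


@dataclass
class MarkerTable:
    """Per-(cluster, gene) differential-expression ranking."""

    table: pd.DataFrame     # columns: cluster, gene_id, statistic, lfc,
                            #          pvalue, padj, rank

    def top(self, n: int = 10) -> pd.DataFrame:
        return (
            self.table[self.table["rank"] <= n]
            .sort_values(["cluster", "rank"])
            .reset_index(drop=True)
        )


def rank_markers(expr: ExpressionMatrix, labels) -> MarkerTable:
    """One-vs-rest Wilcoxon rank-sum marker ranking with BH adjustment.

    For each cluster k and gene g the cluster's values are tested against
    all other spots (two-sided; exact null for small groups without ties,
    normal approximation otherwise).  The reported statistic is the rank
    sum of the cluster group.  The log fold-change is the difference of
    group means, appropriate for log-scale (or standardized) input.  Within
    each cluster, p-values are BH-adjusted across genes and genes ranked by
    ascending adjusted p, ties by descending \\|lfc\\| then gene order.
    """
    labels = np.asarray(labels)
    X = expr.values
    if len(labels) != X.shape[0]:
        raise ValueError("labels length must match the number of rows")
    clusters = np.unique(labels)
    for k in clusters:
        if np.count_nonzero(labels == k) < 2:
            raise ValueError(f"cluster {k} has fewer than 2 members")

    rows = []
    for k in clusters:
        in_k = labels == k
        Xk, Xr = X[in_k], X[~in_k]
        n1 = Xk.shape[0]
        stat = np.empty(X.shape[1])
        pval = np.empty(X.shape[1])
        for g in range(X.shape[1]):
            col_k, col_r = Xk[:, g], Xr[:, g]
            if np.ptp(X[:, g]) == 0:
                warnings.warn(
                    f"gene {expr.gene_ids[g]} is constant; p set to 1",
                    stacklevel=2,
                )
                stat[g] = n1 * (n1 + 1) / 2 + n1 * len(col_r) / 2
                pval[g] = 1.0
                continue
            res = stats.mannwhitneyu(
                col_k, col_r, alternative="two-sided", method="auto"
            )
            # rank-sum of the first group from the Mann-Whitney U statistic
            stat[g] = res.statistic + n1 * (n1 + 1) / 2
            pval[g] = res.pvalue
        lfc = Xk.mean(axis=0) - Xr.mean(axis=0)
        padj = stats.false_discovery_control(pval, method="bh")
        order = np.lexsort((np.arange(X.shape[1]), -np.abs(lfc), padj))
        rank = np.empty(X.shape[1], dtype=int)
        rank[order] = np.arange(1, X.shape[1] + 1)
        for g in range(X.shape[1]):
            rows.append(
                dict(
                    cluster=k, gene_id=expr.gene_ids[g],
                    statistic=stat[g], lfc=lfc[g],
                    pvalue=pval[g], padj=padj[g], rank=rank[g],
                )
            )
    return MarkerTable(pd.DataFrame(rows))
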