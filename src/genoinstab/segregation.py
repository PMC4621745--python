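"""Signature-based clustering and the label-segregation permutation test.

Samples are clustered hierarchically on a signature gene set (distance =
1 - Pearson correlation between sample profiles, average linkage), the
dendrogram is cut at its root into two clusters, and the segregation of a
binary sample label (e.g. driver-mutant vs wild-type) across the two-group
cut is quantified.  The observed statistic is the minimum over the two
clusters of the hypergeometric upper-tail probability of labeled-sample
enrichment; its null distribution comes from permuting the labels while
keeping the clustering fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "Dendrogram",
    "cluster_samples",
    "cut_two",
    "SegregationResult",
    "segregation_pvalue",
]

MIN_SIGNATURE_GENES = 10


@dataclass
class Dendrogram:
    """An average-linkage dendrogram over samples with a fixed sample order."""

    linkage: np.ndarray
    sample_ids: list[str]
    genes_used: list[str]


def cluster_samples(expr: pd.DataFrame, signature: Sequence[str]) -> Dendrogram:
    """Hierarchical clustering of samples restricted to a signature gene set.

    ``expr`` is genes x samples.  At least 10 signature genes must be
    present in the matrix; missing genes are reported in the error.  Samples
    are processed in lexicographic order so the result is invariant to the
    input column order.
    """
    signature = set(signature)
    matched = sorted(signature & set(expr.index))
    if len(matched) < MIN_SIGNATURE_GENES:
        missing = sorted(signature - set(expr.index))
        raise ValueError(
            f"only {len(matched)} signature genes matched the expression matrix "
            f"(need >= {MIN_SIGNATURE_GENES}); missing: {missing}"
        )
    sample_ids = sorted(str(s) for s in expr.columns)
    mat = expr.loc[matched, sample_ids].to_numpy(dtype=float).T  # samples x genes
    dist = pdist(mat, metric="correlation")  # 1 - Pearson r between sample profiles
    linkage = hierarchy.linkage(dist, method="average")
    return Dendrogram(linkage, sample_ids, matched)


def cut_two(dendrogram: Dendrogram) -> pd.Series:
    """Cut the dendrogram at its root into exactly two clusters.

    Cluster 1 is the smaller of the two; on a size tie, cluster 1 is the one
    containing the lexicographically first sample.
    """
    n = len(dendrogram.sample_ids)
    if n < 2:
        raise ValueError("need at least 2 samples to cut")
    assignment = hierarchy.cut_tree(dendrogram.linkage, n_clusters=2).ravel()
    sizes = np.bincount(assignment, minlength=2)
    first = assignment[0]  # sample_ids are sorted, so index 0 is lexicographic first
    if sizes[0] < sizes[1]:
        small = 0
    elif sizes[1] < sizes[0]:
        small = 1
    else:
        small = first
    labels = np.where(assignment == small, 1, 2)
    return pd.Series(labels, index=pd.Index(dendrogram.sample_ids, name="sample_id"),
                     name="cluster")


@dataclass
class SegregationResult:
    """Permutation-calibrated min-hypergeometric segregation result."""

    cluster_sizes: tuple[int, int]
    labeled_per_cluster: tuple[int, int]
    observed_statistic: float
    p_value: float
    n_permutations: int
    seed: int


def _min_hypergeom_stat(k1: int, n1: int, big_k: int, n: int) -> float:
    """min over the two clusters of P(X >= observed labeled count)."""
    k2, n2 = big_k - k1, n - n1
    p1 = stats.hypergeom.sf(k1 - 1, n, big_k, n1)
    p2 = stats.hypergeom.sf(k2 - 1, n, big_k, n2)
    return float(min(p1, p2))


def segregation_pvalue(
    cluster_labels: pd.Series,
    mutation_labels: pd.Series,
    n_permutations: int = 10000,
    seed: int = 0,
) -> SegregationResult:
    """Permutation p-value for segregation of a binary label across two clusters.

    The statistic is the minimum over the two clusters of the hypergeometric
    upper-tail enrichment probability of labeled samples.  The null keeps
    the clustering fixed and permutes the labels; because the statistic
    depends only on how many labeled samples land in cluster 1, the
    permutation draw is realized exactly by sampling that count from its
    hypergeometric distribution.  p = (1 + #{null <= observed}) /
    (n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    cluster_labels, mutation_labels = cluster_labels.align(mutation_labels, join="inner")
    if len(cluster_labels) == 0:
        raise ValueError("no shared samples between cluster and mutation labels")
    clusters = cluster_labels.to_numpy()
    labeled = mutation_labels.to_numpy(dtype=int)
    if labeled.sum() < 1:
        raise ValueError("need at least one labeled sample")
    n = clusters.size
    n1 = int(np.sum(clusters == 1))
    big_k = int(labeled.sum())
    k1 = int(np.sum(labeled[clusters == 1]))
    observed = _min_hypergeom_stat(k1, n1, big_k, n)

    # permutation null: labeled count in cluster 1 is hypergeometric
    xs = np.arange(max(0, big_k - (n - n1)), min(big_k, n1) + 1)
    stat_by_x = np.array([_min_hypergeom_stat(int(x), n1, big_k, n) for x in xs])
    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(big_k, n - big_k, n1, size=n_permutations)
    null = stat_by_x[draws - xs[0]]
    p = (1 + int(np.sum(null <= observed + 1e-15))) / (n_permutations + 1)
    return SegregationResult(
        cluster_sizes=(n1, n - n1),
        labeled_per_cluster=(k1, big_k - k1),
        observed_statistic=observed,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )
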