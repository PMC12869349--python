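"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own code paths: brute-force Ward
agglomeration that recomputes within-cluster sums of squares at every
merge, a literal running-sum single-sample GSEA, and exact rank-sum
p-values by enumeration of rank assignments.
"""

from itertools import combinations

import numpy as np


def _cluster_ss(X: np.ndarray, members: list[int]) -> float:
    pts = X[members]
    centroid = pts.mean(axis=0)
    return float(((pts - centroid) ** 2).sum())


def brute_force_ward_partition(X: np.ndarray, k: int) -> set[frozenset]:
    """Agglomerate by minimum increase in total within-cluster SS.

    At every step the merge cost of each cluster pair is recomputed from
    the raw points; ties break toward the lexicographically smallest pair
    of cluster indices. Returns the k-cluster partition as a set of
    frozensets of row indices.
    """
    clusters: list[list[int]] = [[i] for i in range(len(X))]
    ss = [0.0] * len(X)
    while len(clusters) > k:
        best = None
        for (i, a), (j, b) in combinations(enumerate(clusters), 2):
            merged_ss = _cluster_ss(X, a + b)
            delta = merged_ss - ss[i] - ss[j]
            if best is None or delta < best[0] - 1e-15:
                best = (delta, i, j, merged_ss)
        _, i, j, merged_ss = best
        clusters[i] = clusters[i] + clusters[j]
        ss[i] = merged_ss
        del clusters[j], ss[j]
    return {frozenset(c) for c in clusters}


def ssgsea_running_sum(
    expression: np.ndarray, in_set: np.ndarray, alpha: float
) -> float:
    """Literal single-sample GSEA statistic for one sample.

    Ranks genes (average ties), walks them from the highest rank down,
    and accumulates the difference between the weighted in-set CDF and
    the unweighted out-set CDF, step by step.
    """
    from scipy.stats import rankdata

    n = len(expression)
    ranks = rankdata(expression)
    order = sorted(range(n), key=lambda g: -ranks[g])
    sum_w = sum(abs(ranks[g]) ** alpha for g in order if in_set[g])
    n_out = sum(1 for g in order if not in_set[g])
    es = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for g in order:
        if in_set[g]:
            cum_in += abs(ranks[g]) ** alpha / sum_w
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


def exact_ranksum_two_sided_p(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating all rank assignments.

    Valid only for tie-free pooled data. The p-value is the fraction of
    the C(n1+n2, n1) equally likely assignments of ranks to the first
    group whose rank sum is at least as extreme (two-sided, by distance
    from the mean rank sum) as the observed one.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    assert len(np.unique(pooled)) == len(pooled), "oracle requires no ties"
    n1, n = len(a), len(pooled)
    ranks = pooled.argsort().argsort() + 1
    observed = ranks[:n1].sum()
    mean = n1 * (n + 1) / 2
    extreme = 0
    total = 0
    for combo in combinations(range(n), n1):
        s = sum(ranks[list(combo)])
        total += 1
        if abs(s - mean) >= abs(observed - mean) - 1e-12:
            extreme += 1
    return extreme / total


def pearson_residuals_direct(obs: np.ndarray):
    """Element-by-element evaluation of (obs - exp) / sqrt(exp)."""
    obs = np.asarray(obs, float)
    total = obs.sum()
    out = np.empty_like(obs)
    exp = np.empty_like(obs)
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = obs[i].sum() * obs[:, j].sum() / total
            exp[i, j] = e
            out[i, j] = (obs[i, j] - e) / np.sqrt(e)
    return out, exp
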