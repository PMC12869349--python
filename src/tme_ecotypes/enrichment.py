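"""Enrichment and group-comparison statistics.

Pearson residuals of contingency tables (enrichment/depletion of cell
clusters across groups), rank-based group tests on per-sample fractions,
one-vs-rest differential expression markers and lineage-specificity
refinement of marker signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import GeneSignature

__all__ = [
    "ResidualMatrix",
    "GroupTestResult",
    "pearson_residuals",
    "proportion_group_test",
    "de_markers",
    "refine_signature",
    "bh_adjust",
]


@dataclass
class ResidualMatrix:
    """Pearson residuals ``(obs - exp) / sqrt(exp)`` of a contingency table.

    Positive residuals indicate relative enrichment of a column category
    in a row group, negative residuals depletion. ``chi2`` is the Pearson
    chi-square statistic of the table (equals the sum of squared
    residuals).
    """

    residuals: pd.DataFrame
    expected: pd.DataFrame
    observed: pd.DataFrame
    chi2: float


def pearson_residuals(table: pd.DataFrame | np.ndarray) -> ResidualMatrix:
    """Pearson residuals for every cell of a contingency table.

    ``exp[i, j] = rowsum_i * colsum_j / N``; ``R = (obs - exp) / sqrt(exp)``.

    Raises
    ------
    ValueError
        On negative counts, an empty table, or an all-zero row/column
        (the expected count would vanish).
    """
    obs = pd.DataFrame(table).astype(float)
    if obs.size == 0 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    arr = obs.to_numpy()
    if (arr < 0).any():
        raise ValueError("contingency table contains negative counts")
    total = arr.sum()
    if total <= 0:
        raise ValueError("contingency table is empty")
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("contingency table has an all-zero row or column")
    expected = np.outer(row, col) / total
    resid = (arr - expected) / np.sqrt(expected)
    return ResidualMatrix(
        residuals=pd.DataFrame(resid, index=obs.index, columns=obs.columns),
        expected=pd.DataFrame(expected, index=obs.index, columns=obs.columns),
        observed=obs,
        chi2=float((resid**2).sum()),
    )


@dataclass
class GroupTestResult:
    p_value: float
    statistic: float
    direction: int  # sign of median(first) - median(second); 0 for >2 groups
    method: str
    group_names: tuple


def proportion_group_test(
    per_sample_fractions: dict[str, np.ndarray] | pd.DataFrame,
) -> GroupTestResult:
    """Two-sided rank test of per-sample fractions across groups.

    Two groups: Wilcoxon rank-sum (Mann-Whitney U), exact when both
    groups have <= 25 observations and the pooled data has no ties,
    otherwise the normal approximation with tie correction. Three or
    more groups: Kruskal-Wallis.
    """
    if isinstance(per_sample_fractions, pd.DataFrame):
        groups = {
            str(g): sub.iloc[:, -1].to_numpy()
            for g, sub in per_sample_fractions.groupby(
                per_sample_fractions.columns[0]
            )
        }
    else:
        groups = {str(k): np.asarray(v, dtype=float) for k, v in per_sample_fractions.items()}
    names = tuple(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if vals.size == 0:
            raise ValueError(f"group {name!r} is empty")

    if len(names) == 2:
        a, b = groups[names[0]], groups[names[1]]
        pooled = np.concatenate([a, b])
        no_ties = len(np.unique(pooled)) == len(pooled)
        exact = no_ties and len(a) <= 25 and len(b) <= 25
        method = "exact" if exact else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        direction = int(np.sign(np.median(a) - np.median(b)))
        return GroupTestResult(
            p_value=float(res.pvalue),
            statistic=float(res.statistic),
            direction=direction,
            method=f"wilcoxon_rank_sum_{method}",
            group_names=names,
        )
    res = stats.kruskal(*(groups[n] for n in names))
    return GroupTestResult(
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        direction=0,
        method="kruskal_wallis",
        group_names=names,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")


def de_markers(
    expr: pd.DataFrame,
    labels,
    lfc_min: float = 0.4,
    alpha: float = 0.05,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest marker genes per cluster.

    Parameters
    ----------
    expr:
        Log-normalized genes x cells matrix.
    labels:
        Cluster label per cell (aligned with ``expr`` columns).
    lfc_min, alpha:
        A gene is ``kept`` iff its log2 fold change exceeds ``lfc_min``
        and its BH-adjusted p-value (within the contrast) is below
        ``alpha``.

    Notes
    -----
    The test is a two-sided Wilcoxon rank-sum per gene. Log2 fold change
    is computed on ``expm1`` means with a pseudocount of 1 (the scheme
    used by the common single-cell toolkits). Clusters with fewer than
    ``min_cells`` cells are skipped with a warning.
    """
    labels = np.asarray(labels)
    if expr.shape[1] != labels.size:
        raise ValueError("labels must align with expression columns")
    clusters = pd.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")

    X = expr.to_numpy(dtype=float)
    lin = np.expm1(X)
    rows = []
    for cl in clusters:
        mask = labels == cl
        if mask.sum() < min_cells:
            warnings.warn(f"cluster {cl!r} has < {min_cells} cells; skipped", stacklevel=2)
            continue
        in_m = lin[:, mask].mean(axis=1)
        out_m = lin[:, ~mask].mean(axis=1)
        log2fc = np.log2(in_m + 1.0) - np.log2(out_m + 1.0)
        res = stats.mannwhitneyu(
            X[:, mask], X[:, ~mask], alternative="two-sided", axis=1,
            method="asymptotic",
        )
        padj = bh_adjust(res.pvalue)
        kept = (log2fc > lfc_min) & (padj < alpha)
        rows.append(
            pd.DataFrame(
                {
                    "gene": expr.index,
                    "cluster": cl,
                    "log2fc": log2fc,
                    "pval": res.pvalue,
                    "padj": padj,
                    "kept": kept,
                }
            )
        )
    if not rows:
        raise ValueError("no cluster passed the minimum-cell filter")
    return pd.concat(rows, ignore_index=True)


def refine_signature(
    markers: pd.DataFrame,
    lineage_means: pd.DataFrame,
    cluster,
    target_lineage: str,
    max_other_ratio: float = 0.5,
    name: str | None = None,
) -> GeneSignature:
    """Drop marker genes that are also high in other major lineages.

    A kept marker of ``cluster`` survives iff, for every non-target
    lineage, its mean expression there is at most ``max_other_ratio``
    times its mean in ``target_lineage``.

    ``lineage_means`` is a genes x lineages matrix of mean expression.
    Returns a (possibly empty, with warning) :class:`GeneSignature`.
    """
    if target_lineage not in lineage_means.columns:
        raise ValueError(f"unknown target lineage {target_lineage!r}")
    kept = markers[(markers["cluster"] == cluster) & markers["kept"]]
    genes = [g for g in kept["gene"] if g in lineage_means.index]
    others = [c for c in lineage_means.columns if c != target_lineage]
    refined = []
    for g in genes:
        tgt = lineage_means.at[g, target_lineage]
        if tgt <= 0:
            continue
        if all(lineage_means.at[g, o] <= max_other_ratio * tgt for o in others):
            refined.append(g)
    sig_name = name or str(cluster)
    if not refined:
        warnings.warn(f"refined signature {sig_name!r} is empty", stacklevel=2)
    return GeneSignature(name=sig_name, genes=tuple(refined), source="marker_derived")
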