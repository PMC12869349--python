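"""Sample-by-subtype composition matrices and ecotype inference.

The workflow is: tally per-sample cell-subtype fractions, standardize each
subtype column across samples, cluster samples with Ward's minimum-variance
criterion on Euclidean distances (the ``ward.D2`` convention), cut the tree
into ``k`` ecotypes, and summarise how clinical groups distribute across
ecotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage, to_tree

__all__ = [
    "CompositionMatrix",
    "ScaledComposition",
    "EcotypeModel",
    "EcotypeGroupDistribution",
    "build_composition",
    "scale_composition",
    "infer_ecotypes",
    "ecotype_group_distribution",
    "export_dendrogram",
    "label_ecotypes_by_lineage",
    "silhouette_scan",
]

LEVELS = ("subtype", "lineage")
DENOMINATORS = ("all_cells", "parent_lineage")


@dataclass
class CompositionMatrix:
    """Fractions of cell subtypes per sample.

    ``fractions`` is a samples x subtypes DataFrame. With
    ``denominator='all_cells'`` each row sums to 1; with
    ``'parent_lineage'`` each lineage block of a row sums to 1 (for
    lineages present in the sample).
    """

    fractions: pd.DataFrame
    denominator: str = "all_cells"
    lineage_map: dict[str, str] | None = None

    @property
    def samples(self) -> list:
        return list(self.fractions.index)

    @property
    def subtypes(self) -> list:
        return list(self.fractions.columns)


@dataclass
class ScaledComposition:
    """Per-subtype z-standardized composition (constant columns -> zeros)."""

    matrix: pd.DataFrame
    center: pd.Series
    spread: pd.Series


@dataclass
class EcotypeModel:
    """Ward linkage tree with a k-cut into ecotypes.

    ``assignments`` maps sample id -> ecotype label; labels are "E1",
    "E2", ... ordered by ecotype size, largest first.
    """

    linkage: np.ndarray
    k: int
    assignments: pd.Series
    ordering: list
    names: dict[str, str] = field(default_factory=dict)

    @property
    def ecotypes(self) -> list[str]:
        sizes = self.assignments.value_counts()
        return list(sizes.index)


@dataclass
class EcotypeGroupDistribution:
    """Cross-tabulation of ecotypes against a clinical grouping."""

    counts: pd.DataFrame              # ecotype x group
    ecotype_percent: pd.DataFrame     # rows sum to 100 (share of groups within ecotype)
    group_percent: pd.DataFrame       # group x ecotype, rows sum to 100


def build_composition(
    cells: pd.DataFrame,
    level: str = "subtype",
    denominator: str = "all_cells",
) -> CompositionMatrix:
    """Tally per-sample fractions of cell subtypes (or lineages).

    Parameters
    ----------
    cells:
        Post-QC cell table with ``sample_id``, ``subtype`` and (for
        lineage-level analyses) ``lineage`` columns.
    level:
        ``'subtype'`` or ``'lineage'`` — which label defines the columns.
    denominator:
        ``'all_cells'`` divides by the sample's total cell count;
        ``'parent_lineage'`` divides each subtype by the cell count of
        its parent lineage within the sample.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    if denominator not in DENOMINATORS:
        raise ValueError(
            f"unknown denominator {denominator!r}; expected one of {DENOMINATORS}"
        )
    if level not in cells.columns:
        raise ValueError(f"cell table lacks a {level!r} column")

    counts = (
        cells.groupby(["sample_id", level], sort=True, observed=True)
        .size()
        .unstack(fill_value=0)
    )
    counts.columns = counts.columns.astype(str)
    counts.columns.name = level
    counts.index.name = "sample_id"

    lineage_map = None
    if denominator == "all_cells":
        totals = counts.sum(axis=1)
        empty = totals == 0
        if empty.any():
            warnings.warn(
                f"dropping {int(empty.sum())} sample(s) with zero cells",
                stacklevel=2,
            )
            counts = counts[~empty]
            totals = totals[~empty]
        fractions = counts.div(totals, axis=0)
    else:
        if level != "subtype":
            raise ValueError("parent_lineage denominator requires level='subtype'")
        if "lineage" not in cells.columns:
            raise ValueError("parent_lineage denominator requires a 'lineage' column")
        pairs = cells[["subtype", "lineage"]].drop_duplicates()
        dup = pairs["subtype"].duplicated()
        if dup.any():
            raise ValueError(
                "subtypes mapped to multiple lineages: "
                f"{sorted(pairs.loc[dup, 'subtype'])}"
            )
        lineage_map = dict(
            zip(pairs["subtype"].astype(str), pairs["lineage"].astype(str))
        )
        lin_counts = (
            cells.groupby(["sample_id", "lineage"], sort=True, observed=True)
            .size()
            .unstack(fill_value=0)
        )
        denom = pd.DataFrame(
            {st: lin_counts[lineage_map[st]] for st in counts.columns},
            index=counts.index,
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            fractions = counts / denom
        fractions = fractions.fillna(0.0)  # lineage absent from sample
    return CompositionMatrix(
        fractions=fractions, denominator=denominator, lineage_map=lineage_map
    )


def scale_composition(comp: CompositionMatrix | pd.DataFrame) -> ScaledComposition:
    """Standardize each subtype column across samples.

    Uses the sample standard deviation (ddof=1, matching R ``scale()``).
    Columns with zero spread are mapped to all zeros.
    """
    frac = comp.fractions if isinstance(comp, CompositionMatrix) else comp
    if len(frac) < 2:
        raise ValueError("scaling requires at least 2 samples")
    center = frac.mean(axis=0)
    spread = frac.std(axis=0, ddof=1)
    safe = spread.replace(0.0, np.nan)
    scaled = frac.sub(center, axis=1).div(safe, axis=1).fillna(0.0)
    return ScaledComposition(matrix=scaled, center=center, spread=spread)


def infer_ecotypes(scaled: ScaledComposition | pd.DataFrame, k: int) -> EcotypeModel:
    """Ward hierarchical clustering of samples, cut into ``k`` ecotypes.

    Agglomeration uses Ward's minimum-variance criterion on unsquared
    Euclidean distances between sample rows (the ``ward.D2`` convention:
    each merge minimizes the increase in total within-cluster sum of
    squares). Ecotype labels are assigned by cluster size, descending.
    """
    mat = scaled.matrix if isinstance(scaled, ScaledComposition) else scaled
    n = len(mat)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must lie in [1, {n}]")
    X = mat.to_numpy(dtype=float)
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    order = [mat.index[i] for i in leaves_list(Z)]

    sizes = pd.Series(raw).value_counts()
    # stable relabel: size desc, then first-appearance for ties
    first_seen = {c: int(np.argmax(raw == c)) for c in sizes.index}
    ranked = sorted(sizes.index, key=lambda c: (-sizes[c], first_seen[c]))
    relabel = {c: f"E{i + 1}" for i, c in enumerate(ranked)}
    assignments = pd.Series(
        [relabel[c] for c in raw], index=mat.index, name="ecotype"
    )
    return EcotypeModel(linkage=Z, k=k, assignments=assignments, ordering=order)


def ecotype_group_distribution(
    model: EcotypeModel, samples: pd.DataFrame, by: str = "stage"
) -> EcotypeGroupDistribution:
    """Count/percentage tables of a clinical grouping across ecotypes.

    ``by`` is ``'stage'``, ``'cancer_type'`` or ``'cancer_type:stage'``.
    Raises if any assigned sample lacks metadata.
    """
    meta = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    missing = [s for s in model.assignments.index if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")

    if by in ("cancer_type:stage", "cancer_type×stage"):
        group = (
            meta.loc[model.assignments.index, "cancer_type"].astype(str)
            + ":"
            + meta.loc[model.assignments.index, "stage"].astype(str)
        )
    else:
        if by not in meta.columns:
            raise ValueError(f"metadata lacks grouping column {by!r}")
        group = meta.loc[model.assignments.index, by].astype(str)

    counts = pd.crosstab(model.assignments, group)
    counts.index.name = "ecotype"
    counts.columns.name = by
    eco_pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    grp_counts = counts.T
    grp_pct = grp_counts.div(grp_counts.sum(axis=1), axis=0) * 100.0
    return EcotypeGroupDistribution(
        counts=counts, ecotype_percent=eco_pct, group_percent=grp_pct
    )


def label_ecotypes_by_lineage(
    model: EcotypeModel,
    comp: CompositionMatrix,
    lineage_map: dict[str, str],
    archetypes: dict[str, str] | None = None,
) -> dict[str, str]:
    """Post-hoc ecotype naming by dominant mean lineage fraction.

    ``archetypes`` maps lineage -> human label, e.g. ``{"T_NK":
    "T_cell_dominant", "Tumour": "desert"}``; lineages not listed fall
    back to ``"<lineage>_enriched"``. The mapping is annotation only and
    never feeds back into clustering.
    """
    lin_frac = (
        comp.fractions.T.groupby(
            pd.Series({c: lineage_map[c] for c in comp.fractions.columns})
        )
        .sum()
        .T
    )
    names = {}
    for eco in sorted(model.assignments.unique()):
        members = model.assignments.index[model.assignments == eco]
        dominant = lin_frac.loc[members].mean(axis=0).idxmax()
        if archetypes and dominant in archetypes:
            names[eco] = archetypes[dominant]
        else:
            names[eco] = f"{dominant}_enriched"
    model.names = names
    return names


def silhouette_scan(
    scaled: ScaledComposition | pd.DataFrame, k_range=range(2, 11)
) -> pd.Series:
    """Mean silhouette width of the Ward k-cut for each k (report only)."""
    from sklearn.metrics import silhouette_score

    mat = scaled.matrix if isinstance(scaled, ScaledComposition) else scaled
    X = mat.to_numpy(dtype=float)
    Z = linkage(X, method="ward")
    out = {}
    for k in k_range:
        if k >= len(mat):
            break
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        out[k] = float(silhouette_score(X, labels))
    return pd.Series(out, name="silhouette")


def export_dendrogram(model: EcotypeModel) -> str:
    """Newick string for the sample dendrogram.

    Internal nodes sit at half the Ward merge height (the usual
    hclust-to-phylo convention), so two leaves merged at height ``h``
    each get a branch of length ``h/2``.
    """
    tree = to_tree(model.linkage)
    labels = list(model.assignments.index)

    def node_height(node) -> float:
        return node.dist / 2.0

    def render(node, parent_height: float) -> str:
        length = parent_height - node_height(node)
        if node.is_leaf():
            name = str(labels[node.id]).replace(" ", "_")
            return f"{name}:{length:.10g}"
        left = render(node.left, node_height(node))
        right = render(node.right, node_height(node))
        return f"({left},{right}):{length:.10g}"

    if tree.is_leaf():
        return f"{labels[tree.id]};"
    left = render(tree.left, node_height(tree))
    right = render(tree.right, node_height(tree))
    return f"({left},{right});"
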