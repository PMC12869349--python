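"""Per-sample cell quality filtering.

Cells are removed when they fail any of four rules:

* an absolute minimum number of detected genes,
* per-sample robust lower thresholds (median minus a multiple of the
  median absolute deviation) on UMI counts, detected genes and
  detected housekeeping genes,
* a ceiling on the mitochondrial transcript fraction,
* an optional pre-computed doublet flag (``is_doublet`` column), if present.

Per-sample thresholds are computed on the *full* sample before any cell is
removed. Re-applying the filter to an already filtered table therefore
recomputes thresholds on the survivors and may remove further cells; the
operation is deliberately not idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCThresholds",
    "QCReport",
    "robust_lower_threshold",
    "apply_qc",
    "REQUIRED_COLUMNS",
]

#: Columns every cell table must carry.
REQUIRED_COLUMNS = (
    "cell_id",
    "sample_id",
    "umi_count",
    "gene_count",
    "housekeeping_count",
    "mito_fraction",
)

#: Metrics that get a per-sample robust lower threshold.
MAD_METRICS = ("umi_count", "gene_count", "housekeeping_count")


@dataclass(frozen=True)
class QCThresholds:
    """Filter parameters.

    ``mad_scale`` is the MAD consistency constant; the default 1.4826 makes
    the MAD a consistent estimator of the standard deviation under
    normality (matching R's ``mad()``). Set it to 1.0 for a raw MAD.
    """

    min_genes: int = 200
    mad_multiplier: float = 3.0
    max_mito: float = 0.20
    mad_scale: float = 1.4826

    def __post_init__(self) -> None:
        if self.min_genes <= 0:
            raise ValueError("min_genes must be positive")
        if self.mad_multiplier <= 0:
            raise ValueError("mad_multiplier must be positive")
        if not 0 < self.max_mito:
            raise ValueError("max_mito must be positive")
        if self.mad_scale <= 0:
            raise ValueError("mad_scale must be positive")


def robust_lower_threshold(
    values, multiplier: float = 3.0, mad_scale: float = 1.4826
) -> float:
    """``median(values) - multiplier * mad_scale * MAD(values)``.

    ``MAD`` here is the raw median absolute deviation from the median;
    ``mad_scale`` is applied on top (1.4826 for normal consistency).

    Raises
    ------
    ValueError
        If ``values`` is empty.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("robust_lower_threshold requires at least one value")
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    return med - multiplier * mad_scale * mad


@dataclass
class QCReport:
    """Outcome of :func:`apply_qc`.

    Attributes
    ----------
    flags:
        One row per cell: per-rule boolean fail columns
        (``fail_min_genes``, ``fail_low_umi``, ``fail_low_genes``,
        ``fail_low_housekeeping``, ``fail_max_mito``, ``fail_doublet``),
        a ``keep`` boolean and a comma-joined ``failed_rules`` string.
    sample_thresholds:
        Per-sample computed lower thresholds, one row per sample, one
        column per MAD-filtered metric.
    removed_per_rule:
        Number of cells failing each rule (a cell can count toward
        several rules).
    thresholds:
        The parameters used.
    """

    flags: pd.DataFrame
    sample_thresholds: pd.DataFrame
    removed_per_rule: dict[str, int]
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    @property
    def n_kept(self) -> int:
        return int(self.flags["keep"].sum())

    @property
    def n_removed(self) -> int:
        return int((~self.flags["keep"]).sum())

    def kept_cells(self, cells: pd.DataFrame) -> pd.DataFrame:
        """Subset ``cells`` to the cells that passed every rule."""
        keep_ids = set(self.flags.loc[self.flags["keep"], "cell_id"])
        return cells[cells["cell_id"].isin(keep_ids)].copy()

    def summary(self) -> dict:
        return {
            "n_cells": int(len(self.flags)),
            "n_kept": self.n_kept,
            "n_removed": self.n_removed,
            "removed_per_rule": dict(self.removed_per_rule),
            "parameters": {
                "min_genes": self.thresholds.min_genes,
                "mad_multiplier": self.thresholds.mad_multiplier,
                "max_mito": self.thresholds.max_mito,
                "mad_scale": self.thresholds.mad_scale,
            },
        }


def _validate_cells(cells: pd.DataFrame) -> None:
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in cells.columns]
    if missing_cols:
        raise ValueError(f"cell table is missing columns: {missing_cols}")
    for col in REQUIRED_COLUMNS[2:]:
        bad = cells[col].isna()
        if bad.any():
            offender = cells.loc[bad, "cell_id"].iloc[0]
            raise ValueError(f"cell {offender!r} has missing metric {col!r}")
    if (cells["mito_fraction"].lt(0) | cells["mito_fraction"].gt(1)).any():
        raise ValueError("mito_fraction must lie in [0, 1]")


def apply_qc(cells: pd.DataFrame, thresholds: QCThresholds | None = None) -> QCReport:
    """Flag every cell against the QC rules.

    A cell fails iff ``gene_count < min_genes``, or any of UMI count,
    gene count or housekeeping count falls strictly below its per-sample
    robust lower threshold, or ``mito_fraction > max_mito``, or it is
    marked as a doublet. Thresholds are computed per sample on all cells
    of that sample, before any removal.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    _validate_cells(cells)

    thr_rows = {}
    for sample_id, grp in cells.groupby("sample_id", sort=True):
        thr_rows[sample_id] = {
            metric: robust_lower_threshold(
                grp[metric].to_numpy(),
                thresholds.mad_multiplier,
                thresholds.mad_scale,
            )
            for metric in MAD_METRICS
        }
    sample_thresholds = pd.DataFrame.from_dict(thr_rows, orient="index")
    sample_thresholds.index.name = "sample_id"

    per_sample = sample_thresholds.reindex(cells["sample_id"]).to_numpy()
    metric_vals = cells[list(MAD_METRICS)].to_numpy(dtype=float)
    low = metric_vals < per_sample  # strict: at-threshold cells survive

    fails = pd.DataFrame(
        {
            "cell_id": cells["cell_id"].to_numpy(),
            "sample_id": cells["sample_id"].to_numpy(),
            "fail_min_genes": cells["gene_count"].to_numpy() < thresholds.min_genes,
            "fail_low_umi": low[:, 0],
            "fail_low_genes": low[:, 1],
            "fail_low_housekeeping": low[:, 2],
            "fail_max_mito": cells["mito_fraction"].to_numpy() > thresholds.max_mito,
        }
    )
    if "is_doublet" in cells.columns:
        fails["fail_doublet"] = cells["is_doublet"].fillna(False).astype(bool).to_numpy()
    else:
        fails["fail_doublet"] = False

    rule_cols = [c for c in fails.columns if c.startswith("fail_")]
    fail_mat = fails[rule_cols].to_numpy()
    fails["keep"] = ~fail_mat.any(axis=1)
    rule_names = np.array([c.removeprefix("fail_") for c in rule_cols])
    fails["failed_rules"] = [
        ",".join(rule_names[row]) if row.any() else "" for row in fail_mat
    ]

    removed_per_rule = {
        c.removeprefix("fail_"): int(fails[c].sum()) for c in rule_cols
    }
    return QCReport(
        flags=fails,
        sample_thresholds=sample_thresholds,
        removed_per_rule=removed_per_rule,
        thresholds=thresholds,
    )
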