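"""Normalization and gene-signature scoring.

Two scoring schemes are provided:

* binned-control *module scores* (mean of the signature genes minus the
  mean of expression-bin-matched control genes, per cell), and
* single-sample GSEA (*ssGSEA*) rank-based enrichment scores for bulk
  samples.

Also hosts the GMT signature reader/writer, the log-normalization of raw
counts and the bundled signature fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "GeneSignature",
    "NormalizedExpression",
    "ScoreTable",
    "log_normalize",
    "module_score",
    "ssgsea_score",
    "read_gmt",
    "write_gmt",
    "bundled_signatures",
]


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered, duplicate-free gene list."""

    name: str
    genes: tuple[str, ...]
    source: str = "curated"

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class NormalizedExpression:
    """Log-normalized genes x units matrix (natural log of 1 + CP10K)."""

    values: pd.DataFrame
    scale_factor: float = 10_000.0


@dataclass
class ScoreTable:
    """Units x signatures score matrix with a method tag."""

    scores: pd.DataFrame
    method: str
    parameters: dict | None = None


def read_gmt(path) -> list[GeneSignature]:
    """Read gene signatures from a GMT file (name, description, genes...)."""
    sigs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name, description = parts[0], parts[1]
        genes = tuple(dict.fromkeys(g for g in parts[2:] if g))
        source = "marker_derived" if "marker" in description.lower() else "curated"
        sigs.append(GeneSignature(name=name, genes=genes, source=source))
    return sigs


def write_gmt(signatures, path, descriptions: dict[str, str] | None = None) -> None:
    """Write signatures to GMT; description defaults to the source tag."""
    lines = []
    for sig in signatures:
        desc = (descriptions or {}).get(sig.name, sig.source)
        lines.append("\t".join([sig.name, desc, *sig.genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def bundled_signatures() -> list[GeneSignature]:
    """Signature fixtures shipped with the package (cytotoxicity,
    exhaustion/inhibitory, and the refined myeloid subset signatures)."""
    with resources.as_file(
        resources.files("tme_ecotypes").joinpath("data/signatures.gmt")
    ) as p:
        return read_gmt(p)


def log_normalize(
    counts: pd.DataFrame, scale_factor: float = 10_000.0
) -> NormalizedExpression:
    """``ln(1 + count * scale_factor / unit_total)`` per genes x units matrix.

    Raises
    ------
    ValueError
        If any unit (column) has an all-zero count vector, naming it.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = arr.sum(axis=0)
    zero = totals == 0
    if zero.any():
        offender = counts.columns[int(np.argmax(zero))]
        raise ValueError(f"unit {offender!r} has all-zero counts")
    values = np.log1p(arr * scale_factor / totals)
    return NormalizedExpression(
        values=pd.DataFrame(values, index=counts.index, columns=counts.columns),
        scale_factor=float(scale_factor),
    )


def _match_genes(universe: pd.Index, sig: GeneSignature, what: str) -> list:
    """Case-insensitive signature-gene lookup; warns on drops."""
    upper = {str(g).upper(): g for g in universe}
    hits, missing = [], []
    for g in sig.genes:
        key = str(g).upper()
        if key in upper:
            hits.append(upper[key])
        else:
            missing.append(g)
    if missing:
        warnings.warn(
            f"{what}: {len(missing)} gene(s) of {sig.name!r} absent from the "
            f"matrix and dropped: {missing[:5]}{'...' if len(missing) > 5 else ''}",
            stacklevel=3,
        )
    return hits


def module_score(
    expr: NormalizedExpression | pd.DataFrame,
    signatures,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ScoreTable:
    """Binned-control module score per unit (cell) and signature.

    Genes are split into ``n_bins`` bins of (near) equal size by average
    expression across units. For each signature gene, ``n_ctrl`` control
    genes are drawn without replacement from its bin (signature genes
    themselves are excluded from the control pool); the score is the mean
    expression of the signature genes minus the mean of the pooled
    control genes, per unit.
    """
    mat = expr.values if isinstance(expr, NormalizedExpression) else expr
    if isinstance(signatures, GeneSignature):
        signatures = [signatures]
    if n_bins < 1 or n_ctrl < 1:
        raise ValueError("n_bins and n_ctrl must be positive")
    rng = np.random.default_rng(seed)

    avg = mat.to_numpy(dtype=float).mean(axis=1)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(avg), dtype=int)
    for b, idx in enumerate(np.array_split(order, min(n_bins, len(avg)))):
        bin_of[idx] = b
    pos = {g: i for i, g in enumerate(mat.index)}

    out = {}
    X = mat.to_numpy(dtype=float)
    for sig in signatures:
        genes = _match_genes(mat.index, sig, "module_score")
        if not genes:
            raise ValueError(f"no gene of signature {sig.name!r} found in matrix")
        sig_idx = np.array([pos[g] for g in genes])
        sig_set = set(sig_idx.tolist())
        ctrl: set[int] = set()
        for gi in sig_idx:
            pool = np.flatnonzero(bin_of == bin_of[gi])
            pool = pool[[p not in sig_set for p in pool]]
            if pool.size == 0:
                continue
            # draw by (sorted) gene name so scores are invariant to the
            # row order of the input matrix
            pool_names = np.sort(np.asarray(mat.index[pool], dtype=object))
            take = min(n_ctrl, pool_names.size)
            chosen = rng.choice(pool_names, size=take, replace=False)
            ctrl.update(pos[g] for g in chosen)
        if not ctrl:
            raise ValueError(
                f"signature {sig.name!r}: empty control pool (too few genes)"
            )
        ctrl_idx = np.fromiter(ctrl, dtype=int)
        out[sig.name] = X[sig_idx].mean(axis=0) - X[ctrl_idx].mean(axis=0)

    scores = pd.DataFrame(out, index=mat.columns)
    scores.index.name = "unit"
    return ScoreTable(
        scores=scores,
        method="module",
        parameters={"n_bins": n_bins, "n_ctrl": n_ctrl, "seed": seed},
    )


def ssgsea_score(
    expr: pd.DataFrame,
    signatures,
    alpha: float = 0.25,
    normalize: bool = True,
) -> ScoreTable:
    """Single-sample GSEA enrichment scores (samples x signatures).

    Per sample, genes are ranked by expression (ties -> average rank).
    Walking the genes in decreasing-rank order, the score is the sum over
    positions of the difference between the rank\\ :sup:`alpha`-weighted
    in-set empirical CDF and the unweighted out-set empirical CDF. With
    ``normalize`` the whole score matrix is divided by its (max - min).
    Scores depend on expression only through ranks, so any strictly
    increasing per-sample transform leaves them unchanged.
    """
    if isinstance(signatures, GeneSignature):
        signatures = [signatures]
    n_genes = expr.shape[0]
    if n_genes < 2:
        raise ValueError("need at least 2 genes")

    X = expr.to_numpy(dtype=float)
    sig_masks = {}
    for sig in signatures:
        genes = _match_genes(expr.index, sig, "ssgsea_score")
        if not genes:
            raise ValueError(f"no gene of signature {sig.name!r} found in matrix")
        mask = expr.index.isin(genes)
        if mask.all():
            raise ValueError(
                f"signature {sig.name!r} covers every gene (empty complement)"
            )
        sig_masks[sig.name] = mask

    out = {name: np.empty(X.shape[1]) for name in sig_masks}
    for j in range(X.shape[1]):
        r = rankdata(X[:, j])  # 1..n, average ties
        order = np.argsort(-r, kind="stable")
        r_sorted = r[order]
        for name, mask in sig_masks.items():
            in_sorted = mask[order]
            w = np.where(in_sorted, np.abs(r_sorted) ** alpha, 0.0)
            cdf_in = np.cumsum(w) / w.sum()
            steps_out = np.where(in_sorted, 0.0, 1.0)
            cdf_out = np.cumsum(steps_out) / steps_out.sum()
            out[name][j] = float(np.sum(cdf_in - cdf_out))

    scores = pd.DataFrame(out, index=expr.columns)
    scores.index.name = "sample"
    if normalize:
        span = float(scores.to_numpy().max() - scores.to_numpy().min())
        if span > 0:
            scores = scores / span
    return ScoreTable(
        scores=scores,
        method="ssgsea",
        parameters={"alpha": alpha, "normalize": normalize},
    )
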