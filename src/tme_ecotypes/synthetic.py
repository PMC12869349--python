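"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

Samples draw a latent ecotype profile (with stage-dependent weights),
subtype proportions come from the profile's Dirichlet concentration, and
cell counts are multinomial. Per-cell QC metrics follow a correlated
log-normal model with a configurable fraction of planted violations.
Optional layers add a log-normal-Poisson expression matrix with planted
subtype markers and proportional-hazards survival driven by a score.

Everything is reproducible: the same config and seed give byte-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EcotypeProfile",
    "SimulationConfig",
    "SimulatedCohort",
    "default_lineage_table",
    "default_profiles",
    "simulate_cohort",
    "simulate_expression",
    "simulate_survival",
    "write_cohort",
]

#: Major lineages and their default share of the subtype panel.
LINEAGE_WEIGHTS = {
    "Tumour": 6,
    "T_NK": 13,
    "MonoMacro": 9,
    "DC": 2,
    "B_Plasma": 2,
    "Fibroblast": 7,
    "Endothelial": 5,
}

CANCER_TYPES = ("BCC", "SCC", "CM", "AM")
STAGES = ("normal", "early", "advanced")


@dataclass(frozen=True)
class EcotypeProfile:
    """Latent compositional archetype.

    ``concentration`` holds one strictly positive Dirichlet parameter per
    subtype; ``stage_bias`` maps stage -> nonnegative sampling weight
    (not all zero) controlling which stages the profile tends to occur in.
    """

    name: str
    concentration: np.ndarray
    stage_bias: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in STAGES}
    )

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentration, dtype=float)
        object.__setattr__(self, "concentration", conc)
        if conc.ndim != 1 or conc.size < 2:
            raise ValueError(f"profile {self.name!r}: concentration must be a vector")
        if (conc <= 0).any():
            raise ValueError(
                f"profile {self.name!r}: concentration must be strictly positive"
            )
        if any(w < 0 for w in self.stage_bias.values()):
            raise ValueError(f"profile {self.name!r}: stage_bias must be nonnegative")
        if sum(self.stage_bias.values()) <= 0:
            raise ValueError(f"profile {self.name!r}: stage_bias is all zero")


def default_lineage_table(n_subtypes: int = 44) -> pd.DataFrame:
    """Subtype panel with lineage assignment (largest-remainder allocation)."""
    if n_subtypes < len(LINEAGE_WEIGHTS):
        raise ValueError(f"need at least {len(LINEAGE_WEIGHTS)} subtypes")
    total = sum(LINEAGE_WEIGHTS.values())
    raw = {k: n_subtypes * v / total for k, v in LINEAGE_WEIGHTS.items()}
    sizes = {k: int(np.floor(x)) for k, x in raw.items()}
    for k in sizes:
        sizes[k] = max(sizes[k], 1)
    leftovers = sorted(raw, key=lambda k: raw[k] - np.floor(raw[k]), reverse=True)
    i = 0
    while sum(sizes.values()) < n_subtypes:
        sizes[leftovers[i % len(leftovers)]] += 1
        i += 1
    while sum(sizes.values()) > n_subtypes:
        k = max(sizes, key=lambda k: sizes[k])
        sizes[k] -= 1
    rows = []
    for lineage, size in sizes.items():
        for j in range(size):
            rows.append({"subtype": f"{lineage}_c{j + 1:02d}", "lineage": lineage})
    return pd.DataFrame(rows)


def default_profiles(
    n_subtypes: int = 44,
    own_concentration: float = 8.0,
    background: float = 0.4,
    lineage_table: pd.DataFrame | None = None,
) -> list[EcotypeProfile]:
    """Five archetype profiles: T-dominant, stromal, balanced, desert, myeloid.

    The desert profile is advanced-stage-biased and the T-dominant
    profile early-stage-biased, so simulated cohorts reproduce the
    stage-transition pattern qualitatively.
    """
    lt = lineage_table if lineage_table is not None else default_lineage_table(n_subtypes)
    lineages = lt["lineage"].to_numpy()

    def conc(favoured: set[str]) -> np.ndarray:
        return np.where(np.isin(lineages, list(favoured)), own_concentration, background)

    return [
        EcotypeProfile(
            "T_dominant", conc({"T_NK"}),
            {"normal": 0.5, "early": 4.0, "advanced": 0.3},
        ),
        EcotypeProfile(
            "stromal", conc({"Fibroblast", "Endothelial"}),
            {"normal": 1.0, "early": 1.2, "advanced": 0.8},
        ),
        EcotypeProfile(
            "balanced", np.full(len(lineages), 1.5),
            {"normal": 2.0, "early": 1.0, "advanced": 0.4},
        ),
        EcotypeProfile(
            "desert", conc({"Tumour"}),
            {"normal": 0.1, "early": 0.4, "advanced": 4.0},
        ),
        EcotypeProfile(
            "myeloid", conc({"MonoMacro", "DC"}),
            {"normal": 0.5, "early": 0.8, "advanced": 1.2},
        ),
    ]


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator. ``seed`` fixes all randomness."""

    n_samples: int = 100
    n_subtypes: int = 44
    n_cells_per_sample: int | tuple[int, int] = (500, 3000)
    profiles: list[EcotypeProfile] | None = None
    marker_effect: float = 1.5
    hazard_ratio: float = 2.0
    seed: int = 0
    normal_fraction: float = 0.15
    qc_violation_rate: float = 0.02
    n_genes: int = 400
    markers_per_subtype: int = 3
    lineage_table: pd.DataFrame | None = None

    def resolved(self) -> "SimulationConfig":
        """Fill in derived defaults (lineage table, profiles) and validate."""
        if self.n_subtypes < 2:
            raise ValueError("n_subtypes must be >= 2")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0 <= self.normal_fraction < 1:
            raise ValueError("normal_fraction must lie in [0, 1)")
        if not 0 <= self.qc_violation_rate < 1:
            raise ValueError("qc_violation_rate must lie in [0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        lt = (
            self.lineage_table
            if self.lineage_table is not None
            else default_lineage_table(self.n_subtypes)
        )
        if len(lt) != self.n_subtypes:
            raise ValueError("lineage_table length must equal n_subtypes")
        profiles = (
            self.profiles
            if self.profiles is not None
            else default_profiles(self.n_subtypes, lineage_table=lt)
        )
        for p in profiles:
            if p.concentration.size != self.n_subtypes:
                raise ValueError(
                    f"profile {p.name!r} concentration length "
                    f"{p.concentration.size} != n_subtypes {self.n_subtypes}"
                )
        return replace(self, profiles=profiles, lineage_table=lt)

    def cells_range(self) -> tuple[int, int]:
        if isinstance(self.n_cells_per_sample, (tuple, list)):
            lo, hi = self.n_cells_per_sample
        else:
            lo = hi = int(self.n_cells_per_sample)
        if lo < 1 or hi < lo:
            raise ValueError("invalid n_cells_per_sample")
        return int(lo), int(hi)


@dataclass
class SimulatedCohort:
    """Everything the downstream pipeline consumes, plus the ground truth."""

    cells: pd.DataFrame
    samples: pd.DataFrame
    true_ecotype: dict[str, str]
    true_proportions: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    marker_map: dict[str, list[str]] | None = None
    bulk: pd.DataFrame | None = None
    survival: pd.DataFrame | None = None


def _qc_metrics(rng: np.random.Generator, n: int, violation_rate: float) -> pd.DataFrame:
    """Correlated log-normal UMI/gene counts, binomial-thinned housekeeping
    counts, Beta mitochondrial fractions, plus planted violations."""
    mu_umi = rng.normal(np.log(6000.0), 0.25)
    mu_gene = 0.85 * mu_umi
    cov = np.array(
        [
            [0.40**2, 0.9 * 0.40 * 0.35],
            [0.9 * 0.40 * 0.35, 0.35**2],
        ]
    )
    z = rng.multivariate_normal([mu_umi, mu_gene], cov, size=n)
    umi = np.exp(z[:, 0])
    genes = np.exp(z[:, 1])
    genes = np.minimum(genes, umi)  # cannot detect more genes than molecules
    umi = np.maximum(np.round(umi), 1).astype(int)
    genes = np.maximum(np.round(genes), 1).astype(int)
    housekeeping = rng.binomial(genes, 0.06)
    mito = rng.beta(2.0, 20.0, size=n)

    n_bad = rng.binomial(n, violation_rate)
    if n_bad:
        bad = rng.choice(n, size=n_bad, replace=False)
        kind = rng.integers(0, 3, size=n_bad)
        low_gene = bad[kind == 0]
        genes[low_gene] = rng.integers(40, 200, size=low_gene.size)
        umi[low_gene] = np.maximum(genes[low_gene] * 2, umi[low_gene] // 8)
        housekeeping[low_gene] = rng.binomial(genes[low_gene], 0.06)
        high_mito = bad[kind == 1]
        mito[high_mito] = rng.uniform(0.25, 0.6, size=high_mito.size)
        outlier = bad[kind == 2]
        umi[outlier] = np.maximum(umi[outlier] // 10, 1)
        genes[outlier] = np.maximum(genes[outlier] // 10, 1)
        housekeeping[outlier] = rng.binomial(genes[outlier], 0.06)
    return pd.DataFrame(
        {
            "umi_count": umi,
            "gene_count": genes,
            "housekeeping_count": housekeeping,
            "mito_fraction": mito,
        }
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a full annotated cohort from the generative model.

    Per sample: cancer type and stage, then an ecotype profile with
    probability proportional to its stage bias, subtype proportions from
    the profile's Dirichlet, a uniform cell count from the configured
    range, multinomial subtype counts and per-cell QC metrics.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.cells_range()
    lt = cfg.lineage_table
    subtypes = lt["subtype"].to_numpy()
    lineage_of = dict(zip(lt["subtype"], lt["lineage"]))

    sample_rows, cell_frames, truth = [], [], {}
    props_rows = {}
    for i in range(cfg.n_samples):
        sample_id = f"S{i + 1:03d}"
        if rng.random() < cfg.normal_fraction:
            cancer_type, stage = "AdjNormal", "normal"
        else:
            cancer_type = str(rng.choice(CANCER_TYPES))
            stage = "early" if rng.random() < 0.5 else "advanced"
        weights = np.array(
            [p.stage_bias.get(stage, 0.0) for p in cfg.profiles], dtype=float
        )
        if weights.sum() <= 0:
            weights = np.ones(len(cfg.profiles))
        profile = cfg.profiles[rng.choice(len(cfg.profiles), p=weights / weights.sum())]
        truth[sample_id] = profile.name

        props = rng.dirichlet(profile.concentration)
        props_rows[sample_id] = props
        n_cells = int(rng.integers(lo, hi + 1))
        counts = rng.multinomial(n_cells, props)
        subtype_labels = np.repeat(subtypes, counts)

        metrics = _qc_metrics(rng, n_cells, cfg.qc_violation_rate)
        cell_frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{sample_id}_c{j + 1:05d}" for j in range(n_cells)],
                    "sample_id": sample_id,
                    "lineage": [lineage_of[s] for s in subtype_labels],
                    "subtype": subtype_labels,
                    **{c: metrics[c].to_numpy() for c in metrics.columns},
                }
            )
        )
        sample_rows.append(
            {
                "sample_id": sample_id,
                "patient_id": f"P{i + 1:03d}",
                "cancer_type": cancer_type,
                "stage": stage,
            }
        )

    cells = pd.concat(cell_frames, ignore_index=True)
    samples = pd.DataFrame(sample_rows)
    true_proportions = pd.DataFrame.from_dict(
        props_rows, orient="index", columns=subtypes
    )
    true_proportions.index.name = "sample_id"
    return SimulatedCohort(
        cells=cells,
        samples=samples,
        true_ecotype=truth,
        true_proportions=true_proportions,
    )


def simulate_expression(
    cohort: SimulatedCohort, config: SimulationConfig
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Genes x cells counts from a log-normal-Poisson model.

    The first ``markers_per_subtype`` genes of each subtype's marker block
    are elevated by ``marker_effect`` (natural-log fold) in cells of that
    subtype. Returns the counts matrix and the subtype -> marker-gene map;
    both are also stored on the cohort.
    """
    cfg = config.resolved()
    if cohort.cells is None or len(cohort.cells) == 0:
        raise ValueError("cohort has no cells")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))

    subtypes = list(cfg.lineage_table["subtype"])
    n_marker_genes = cfg.markers_per_subtype * len(subtypes)
    n_genes = max(cfg.n_genes, n_marker_genes + 10)
    genes = [f"g{j + 1:04d}" for j in range(n_genes)]
    marker_map = {
        st: genes[k * cfg.markers_per_subtype : (k + 1) * cfg.markers_per_subtype]
        for k, st in enumerate(subtypes)
    }

    n_cells = len(cohort.cells)
    base = rng.normal(np.log(0.5), 0.5, size=n_genes)
    depth = rng.lognormal(0.0, 0.3, size=n_cells)
    noise = rng.normal(0.0, 0.2, size=(n_genes, n_cells))

    subtype_idx = {st: k for k, st in enumerate(subtypes)}
    cell_subtype = cohort.cells["subtype"].map(subtype_idx).to_numpy()
    # marker gene j belongs to subtype j // markers_per_subtype
    marker_owner = np.full(n_genes, -1, dtype=int)
    marker_owner[:n_marker_genes] = np.arange(n_marker_genes) // cfg.markers_per_subtype
    boost = (marker_owner[:, None] == cell_subtype[None, :]) * cfg.marker_effect

    rate = np.exp(base[:, None] + noise + boost) * depth[None, :]
    counts = rng.poisson(rate)
    expr = pd.DataFrame(counts, index=genes, columns=cohort.cells["cell_id"].to_numpy())
    cohort.expression = expr
    cohort.marker_map = marker_map
    return expr, marker_map


def simulate_survival(
    n: int,
    score=None,
    cutoff: float = 0.5,
    hazard_ratio: float = 2.0,
    censor_rate: float = 0.2,
    seed: int = 0,
    baseline_hazard: float = 0.1,
) -> pd.DataFrame:
    """Exponential event times with a proportional-hazards score effect.

    The event hazard is ``baseline_hazard``, multiplied by
    ``hazard_ratio`` when ``score > cutoff``. Censoring is an independent
    exponential with rate ``baseline_hazard * censor_rate / (1 -
    censor_rate)`` (so roughly a ``censor_rate`` fraction of the baseline
    group is censored); ``censor_rate=0`` observes every event.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    rng = np.random.default_rng(seed)
    if score is None:
        score = rng.uniform(0.0, 1.0, size=n)
    score = np.asarray(score, dtype=float)
    if score.size != n:
        raise ValueError("score vector length must equal n")

    hazard = baseline_hazard * np.where(score > cutoff, hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        c_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
        censor_time = rng.exponential(1.0 / c_rate, size=n)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(n, dtype=int)
    return pd.DataFrame(
        {
            "sample_id": [f"B{i + 1:04d}" for i in range(n)],
            "time": time,
            "event": event,
            "score": score,
        }
    )


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict[str, str]:
    """Write the cohort as plain-text artifacts; returns {name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    cells_path = out / "cells.tsv"
    cohort.cells.to_csv(cells_path, sep="\t", index=False)
    written["cells"] = str(cells_path)

    samples_path = out / "samples.tsv"
    cohort.samples.to_csv(samples_path, sep="\t", index=False)
    written["samples"] = str(samples_path)

    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(cohort.true_ecotype, indent=2, sort_keys=True))
    written["truth"] = str(truth_path)

    if cohort.expression is not None:
        from scipy import io as sio
        from scipy.sparse import csr_matrix

        mtx_path = out / "counts.mtx"
        sio.mmwrite(str(mtx_path), csr_matrix(cohort.expression.to_numpy()))
        (out / "features.tsv").write_text("\n".join(cohort.expression.index) + "\n")
        (out / "barcodes.tsv").write_text("\n".join(cohort.expression.columns) + "\n")
        written["counts"] = str(mtx_path)
    if cohort.survival is not None:
        surv_path = out / "survival.csv"
        cohort.survival.to_csv(surv_path, index=False)
        written["survival"] = str(surv_path)
    return written
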