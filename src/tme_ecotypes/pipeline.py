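"""End-to-end orchestration: simulate/ingest -> QC -> composition ->
ecotypes -> enrichment -> (optional) survival, driven by one config dict.

All randomness is funnelled through a single master seed that is expanded
into independent per-stage seeds, so a rerun with the same config is
byte-identical. Each run writes a MANIFEST of completed stages and a JSON
run report with sha256 digests of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition as comp_mod
from . import enrichment as enr_mod
from . import qc as qc_mod
from . import survival as surv_mod
from . import synthetic as syn_mod

log = logging.getLogger("tme_ecotypes")

__all__ = ["run_pipeline", "DEFAULT_CONFIG", "stage_seeds"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"n_samples": 60, "n_subtypes": 44, "n_cells_per_sample": [400, 1200]},
    "inputs": None,  # {"cells": path, "samples": path} to skip simulation
    "qc": {"enabled": True},
    "ecotype": {"k": 5, "level": "subtype", "denominator": "all_cells"},
    "enrichment": {"by": "stage"},
    "survival": {
        "enabled": False,
        "hazard_ratio": 3.0,
        "censor_rate": 0.2,
        "minprop": 0.1,
    },
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic independent per-stage seeds from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(4)
    return {
        "simulate": int(state[0]),
        "survival": int(state[1]),
        "scoring": int(state[2]),
        "spare": int(state[3]),
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: dict | None = None, out_dir="pipeline_out") -> dict:
    """Execute the enabled stages in dependency order.

    Returns the run report (also written to ``report.json``). A stage
    failure raises after recording completed stages in ``MANIFEST``.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(int(cfg["seed"]))

    report: dict = {
        "config": cfg,
        "stage_seeds": seeds,
        "stages": {},
        "warnings": [],
    }
    completed: list[str] = []
    manifest = out / "MANIFEST"

    def finish_stage(name: str, outputs: dict[str, Path], counts: dict | None = None):
        report["stages"][name] = {
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
            "counts": counts or {},
        }
        completed.append(name)
        manifest.write_text("\n".join(completed) + "\n")
        log.info("[%s] done (%s)", name, ", ".join(outputs))

    try:
        # ---- ingest / simulate -------------------------------------------
        if cfg.get("inputs"):
            cells = pd.read_csv(cfg["inputs"]["cells"], sep="\t")
            samples = pd.read_csv(cfg["inputs"]["samples"], sep="\t")
            cohort = None
            finish_stage("ingest", {}, {"cells": len(cells), "samples": len(samples)})
        else:
            sim_cfg = syn_mod.SimulationConfig(
                **{**cfg["simulate"], "seed": seeds["simulate"]}
            )
            cohort = syn_mod.simulate_cohort(sim_cfg)
            cells, samples = cohort.cells, cohort.samples
            paths = syn_mod.write_cohort(cohort, out)
            finish_stage(
                "simulate",
                {k: Path(v) for k, v in paths.items()},
                {"cells": len(cells), "samples": len(samples)},
            )

        # ---- qc ----------------------------------------------------------
        n_cells_in = len(cells)
        if cfg["qc"].get("enabled", True):
            thr = qc_mod.QCThresholds(
                **{
                    k: cfg["qc"][k]
                    for k in ("min_genes", "mad_multiplier", "max_mito", "mad_scale")
                    if k in cfg["qc"]
                }
            )
            qc_report = qc_mod.apply_qc(cells, thr)
            cells = qc_report.kept_cells(cells)
            flags_path = out / "qc_flags.tsv"
            _write_tsv(qc_report.flags, flags_path, index=False)
            summary_path = out / "qc_summary.json"
            summary_path.write_text(
                json.dumps(qc_report.summary(), indent=2, sort_keys=True)
            )
            finish_stage(
                "qc",
                {"flags": flags_path, "summary": summary_path},
                {"cells_in": n_cells_in, "cells_out": len(cells)},
            )
        else:
            report["warnings"].append("qc stage skipped; composition uses raw cells")

        # ---- composition -------------------------------------------------
        eco_cfg = cfg["ecotype"]
        comp = comp_mod.build_composition(
            cells,
            level=eco_cfg.get("level", "subtype"),
            denominator=eco_cfg.get("denominator", "all_cells"),
        )
        scaled = comp_mod.scale_composition(comp)
        comp_path = out / "composition.tsv"
        _write_tsv(comp.fractions, comp_path)
        scaled_path = out / "scaled.tsv"
        _write_tsv(scaled.matrix, scaled_path)
        finish_stage(
            "composition",
            {"composition": comp_path, "scaled": scaled_path},
            {"samples": comp.fractions.shape[0], "subtypes": comp.fractions.shape[1]},
        )

        # ---- ecotypes ----------------------------------------------------
        model = comp_mod.infer_ecotypes(scaled, k=int(eco_cfg.get("k", 5)))
        lineage_map = dict(
            cells[["subtype", "lineage"]].drop_duplicates().to_numpy()
        ) if "lineage" in cells.columns else None
        if lineage_map:
            comp_mod.label_ecotypes_by_lineage(
                model,
                comp,
                lineage_map,
                archetypes={
                    "T_NK": "T_cell_dominant",
                    "Tumour": "desert",
                    "Fibroblast": "stromal",
                    "Endothelial": "stromal",
                    "MonoMacro": "myeloid",
                    "DC": "myeloid",
                },
            )
        assign = model.assignments.to_frame()
        assign["ecotype_name"] = assign["ecotype"].map(model.names or {})
        assign_path = out / "assignments.tsv"
        _write_tsv(assign, assign_path)
        nwk_path = out / "dendrogram.nwk"
        nwk_path.write_text(comp_mod.export_dendrogram(model) + "\n")
        finish_stage(
            "ecotype",
            {"assignments": assign_path, "dendrogram": nwk_path},
            {"k": model.k},
        )

        # ---- enrichment --------------------------------------------------
        by = cfg["enrichment"].get("by", "stage")
        dist = comp_mod.ecotype_group_distribution(model, samples, by=by)
        resid = enr_mod.pearson_residuals(dist.counts)
        dist_path = out / "distribution_counts.tsv"
        _write_tsv(dist.counts, dist_path)
        pct_path = out / "distribution_percent.tsv"
        _write_tsv(dist.ecotype_percent, pct_path)
        resid_path = out / "residuals.tsv"
        _write_tsv(resid.residuals, resid_path)

        tests = []
        if "lineage" in cells.columns and by == "stage":
            lin_comp = comp_mod.build_composition(cells, level="lineage")
            meta = samples.set_index("sample_id")
            stages_here = meta.loc[lin_comp.fractions.index, "stage"]
            for lineage in lin_comp.fractions.columns:
                groups = {
                    "early": lin_comp.fractions.loc[stages_here == "early", lineage].to_numpy(),
                    "advanced": lin_comp.fractions.loc[
                        stages_here == "advanced", lineage
                    ].to_numpy(),
                }
                if min(len(v) for v in groups.values()) == 0:
                    continue
                res = enr_mod.proportion_group_test(groups)
                tests.append(
                    {
                        "lineage": lineage,
                        "p_value": res.p_value,
                        "direction": res.direction,
                        "method": res.method,
                    }
                )
        tests_path = out / "group_tests.tsv"
        _write_tsv(pd.DataFrame(tests), tests_path, index=False)
        finish_stage(
            "enrichment",
            {
                "counts": dist_path,
                "percent": pct_path,
                "residuals": resid_path,
                "group_tests": tests_path,
            },
            {"chi2": resid.chi2},
        )

        # ---- survival (optional) -----------------------------------------
        sv = cfg["survival"]
        if sv.get("enabled", False):
            tumour_frac = (
                cells[cells["lineage"] == "Tumour"].groupby("sample_id").size()
                / cells.groupby("sample_id").size()
            ).fillna(0.0)
            score = tumour_frac.reindex(comp.fractions.index).fillna(0.0).to_numpy()
            surv = syn_mod.simulate_survival(
                n=len(score),
                score=score,
                cutoff=float(np.median(score)),
                hazard_ratio=float(sv.get("hazard_ratio", 3.0)),
                censor_rate=float(sv.get("censor_rate", 0.2)),
                seed=seeds["survival"],
            )
            cut = surv_mod.optimal_cutpoint(surv, minprop=float(sv.get("minprop", 0.1)))
            low = surv[surv["score"] <= cut.cutpoint]
            high = surv[surv["score"] > cut.cutpoint]
            lr = surv_mod.logrank_test(low, high)
            km_path = out / "km_curves.tsv"
            km_frames = []
            for name, grp in (("low", low), ("high", high)):
                f = surv_mod.km_estimate(grp).to_frame()
                f.insert(0, "group", name)
                km_frames.append(f)
            _write_tsv(pd.concat(km_frames, ignore_index=True), km_path, index=False)
            surv_path = out / "survival.csv"
            surv.to_csv(surv_path, index=False)
            cut_path = out / "cutpoint.json"
            cut_path.write_text(
                json.dumps(
                    {
                        "cutpoint": cut.cutpoint,
                        "statistic": cut.statistic,
                        "p_value": cut.p_value,
                        "p_bonferroni": cut.p_bonferroni,
                        "n_low": cut.n_low,
                        "n_high": cut.n_high,
                        "logrank_chi2": lr.statistic,
                        "logrank_p": lr.p_value,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            finish_stage(
                "survival",
                {"survival": surv_path, "km": km_path, "cutpoint": cut_path},
                {"n": len(surv)},
            )
    except Exception as exc:  # annotate with the failing stage, keep partials
        failed_after = completed[-1] if completed else "(none)"
        raise RuntimeError(
            f"pipeline failed after stage {failed_after!r}: {exc}"
        ) from exc

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return report
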