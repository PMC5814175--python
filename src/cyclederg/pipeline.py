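"""End-to-end orchestration of all stages from a single config.

A :class:`RunConfig` (loadable from YAML) toggles the stages, carries all
stage parameters and one master seed, and names an output directory.
Stages run in dependency order: ``simulate`` first (writing fixture files
plus a ground-truth JSON), then the independent analysis stages
``pancancer``, ``survival`` and ``de``, then ``assay``.  A failing stage
aborts its dependents but not independent stages, and the run report is
always written.

All defaults mirror the study thresholds: BH-adjusted p < 0.05 with
|log2FC| > 1 for DE calls, Bonferroni p < 0.05 for enrichment, top/bottom
25% expression strata for survival, p < 0.05 significance elsewhere.
Seeds are logged at INFO so any run is reconstructible.
"""

from __future__ import annotations

import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .data_io import (
    DataValidationError,
    read_expression_matrix,
    read_gmt,
    read_survival_table,
    write_cohort_map,
    write_expression_matrix,
    write_gmt,
    write_run_summary,
    write_survival_table,
)
from .synthetic_data import (
    PanCancerSimConfig,
    SurvivalSimConfig,
    TreatmentSimConfig,
    child_seeds,
    simulate_dose_response,
    simulate_pancancer,
    simulate_qpcr,
    simulate_survival,
    simulate_treatment_microarray,
)
from .geneset_deregulation import cohort_deregulation, pancancer_rank
from .survival_analysis import km_estimate, logrank_test, stratify_quartiles
from .diff_expression import gene_tests, hypergeom_enrichment, overlap_sets
from .assay_quant import bootstrap_ci, fit_4pl, inhibitory_concentration

logger = logging.getLogger("cyclederg")

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline", "load_config"]

ALL_STAGES = ("simulate", "pancancer", "survival", "de", "assay")


@dataclass
class RunConfig:
    out_dir: str = "cyclederg_out"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in ALL_STAGES}
    )
    # analysis inputs; when simulate is enabled and a path is None, the
    # simulated fixture file is used
    expr_path: str | None = None
    cohort_map_path: str | None = None
    geneset_path: str | None = None
    clinical_path: str | None = None
    survival_gene: str | None = None
    de_expr_path: str | None = None
    de_control: str = "control"
    dose_response_path: str | None = None
    qpcr_path: str | None = None
    # stage parameters
    n_perm: int = 10_000
    bh_alpha: float = 0.05
    fc_threshold: float = 1.0
    bonferroni_alpha: float = 0.05
    bootstrap_B: int = 1000
    sim: dict[str, Any] = field(default_factory=dict)


@dataclass
class RunReport:
    status: dict[str, str]  # stage -> ok | failed | skipped
    parameters: dict[str, Any]
    manifest: list[str]
    wall_clock_s: float
    warnings: list[str]

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "status": self.status,
            "parameters": self.parameters,
            "manifest": self.manifest,
            "wall_clock_s": self.wall_clock_s,
            "warnings": self.warnings,
        }


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise DataValidationError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    stages = {s: True for s in ALL_STAGES}
    stages.update(cfg.stages or {})
    cfg.stages = stages
    return cfg


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems: list[str] = []
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        problems.append(f"unknown stages {sorted(unknown)}: remove them")
    if config.n_perm < 1:
        problems.append("n_perm must be >= 1: raise it")
    if not 0 < config.bh_alpha < 1:
        problems.append("bh_alpha must be in (0, 1): fix the threshold")
    if not 0 < config.bonferroni_alpha < 1:
        problems.append("bonferroni_alpha must be in (0, 1): fix the threshold")
    if config.bootstrap_B < 200:
        problems.append("bootstrap_B must be >= 200: raise it")
    if config.seed < 0:
        problems.append("seed must be non-negative: fix it")
    simulated = config.stages.get("simulate", False)
    if config.stages.get("pancancer") and not simulated and not config.expr_path:
        problems.append("pancancer enabled without expr_path: provide a matrix or enable simulate")
    if config.stages.get("pancancer") and not simulated and not config.geneset_path:
        problems.append("pancancer enabled without geneset_path: provide a GMT or enable simulate")
    if config.stages.get("survival") and not simulated and not config.clinical_path:
        problems.append("survival enabled without clinical_path: provide a table or enable simulate")
    if config.stages.get("de") and not simulated and not config.de_expr_path:
        problems.append("de enabled without de_expr_path: provide arrays or enable simulate")
    if config.stages.get("assay") and not simulated and not config.dose_response_path:
        problems.append("assay enabled without dose_response_path: provide a table or enable simulate")
    return problems


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_pipeline(config: RunConfig) -> RunReport:
    """Run all enabled stages; always writes ``report.json`` in out_dir."""
    t0 = time.monotonic()
    problems = validate_config(config)
    if problems:
        raise DataValidationError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed)
    logger.info("master seed %d -> stage seeds %s", config.seed, seeds)

    status: dict[str, str] = {s: "skipped" for s in ALL_STAGES}
    manifest: list[str] = []
    warnings: list[str] = []
    paths = {
        "expr": config.expr_path,
        "cohorts": config.cohort_map_path,
        "geneset": config.geneset_path,
        "clinical": config.clinical_path,
        "de_expr": config.de_expr_path,
        "doseresponse": config.dose_response_path,
        "qpcr": config.qpcr_path,
    }
    sim_failed = False

    def record(p: Path) -> Path:
        manifest.append(str(p))
        return p

    # ---- simulate ---------------------------------------------------
    if config.stages.get("simulate"):
        try:
            sim_dir = out / "sim"
            sim_dir.mkdir(exist_ok=True)
            sim_cfg = dict(config.sim)
            truth: dict[str, Any] = {}

            pc_cfg = PanCancerSimConfig(
                **sim_cfg.get("pancancer", {}), seed=seeds["pancancer"]
            )
            ds, deltas, gset = simulate_pancancer(pc_cfg)
            write_expression_matrix(ds, record(sim_dir / "expression.tsv"), seed=pc_cfg.seed)
            write_cohort_map(ds, record(sim_dir / "cohorts.tsv"))
            write_gmt([gset], record(sim_dir / "geneset.gmt"))
            truth["pancancer_delta"] = deltas

            sv_cfg = SurvivalSimConfig(
                **sim_cfg.get("survival", {}), seed=seeds["survival"]
            )
            cov_rng = np.random.default_rng(seeds["survival"] + 1)
            covariates = cov_rng.normal(8.0, 2.0, size=sv_cfg.n_patients)
            sv_tab = simulate_survival(covariates, sv_cfg)
            write_survival_table(sv_tab, record(sim_dir / "clinical.tsv"), seed=sv_cfg.seed)
            truth["survival_log_hazard_ratio"] = sv_cfg.log_hazard_ratio

            tr_cfg = TreatmentSimConfig(
                **sim_cfg.get("treatment", {}), seed=seeds["treatment"]
            )
            tr_ds, tr_set = simulate_treatment_microarray(tr_cfg)
            write_expression_matrix(tr_ds, record(sim_dir / "treatment.tsv"), seed=tr_cfg.seed)
            write_cohort_map(tr_ds, record(sim_dir / "treatment_design.tsv"))
            write_gmt([tr_set], record(sim_dir / "target_set.gmt"))
            truth["treatment_shifts"] = dict(zip(tr_cfg.conditions, tr_cfg.shifts))

            dr_kw = sim_cfg.get("doseresponse", {})
            dr_params = tuple(dr_kw.get("params", (0.0, 100.0, 3.0, 39.0)))
            dr_doses = dr_kw.get(
                "doses", [1.0, 3.0, 10.0, 20.0, 40.0, 80.0, 160.0]
            )
            dr_tab = simulate_dose_response(
                dr_params, dr_doses, noise_sd=dr_kw.get("noise_sd", 2.0),
                seed=seeds["doseresponse"],
            )
            dr_path = record(sim_dir / "doseresponse.tsv")
            dr_tab.to_csv(dr_path, sep="\t", index=False)
            truth["doseresponse_params"] = list(dr_params)

            qp_kw = sim_cfg.get("qpcr", {})
            qp_tab = simulate_qpcr(
                qp_kw.get("true_folds", {"CDK1": 0.05}),
                noise_sd=qp_kw.get("noise_sd", 0.1),
                seed=seeds["qpcr"],
            )
            qp_path = record(sim_dir / "qpcr.tsv")
            qp_tab.to_csv(qp_path, sep="\t", index=False)
            truth["qpcr_true_folds"] = qp_kw.get("true_folds", {"CDK1": 0.05})

            write_run_summary(truth, record(sim_dir / "truth.json"))
            paths["expr"] = paths["expr"] or str(sim_dir / "expression.tsv")
            paths["cohorts"] = paths["cohorts"] or str(sim_dir / "cohorts.tsv")
            paths["geneset"] = paths["geneset"] or str(sim_dir / "geneset.gmt")
            paths["clinical"] = paths["clinical"] or str(sim_dir / "clinical.tsv")
            paths["de_expr"] = paths["de_expr"] or str(sim_dir / "treatment.tsv")
            paths["doseresponse"] = paths["doseresponse"] or str(sim_dir / "doseresponse.tsv")
            paths["qpcr"] = paths["qpcr"] or str(sim_dir / "qpcr.tsv")
            status["simulate"] = "ok"
        except Exception as exc:  # noqa: BLE001 - recorded in report
            status["simulate"] = "failed"
            sim_failed = True
            warnings.append(f"simulate: {exc}\n{traceback.format_exc(limit=3)}")
            logger.error("simulate stage failed: %s", exc)

    def dependent_blocked(needs_sim: bool) -> bool:
        return needs_sim and sim_failed

    # ---- pancancer --------------------------------------------------
    if config.stages.get("pancancer"):
        if dependent_blocked(config.expr_path is None):
            status["pancancer"] = "skipped"
            warnings.append("pancancer: skipped because simulate failed")
        else:
            try:
                ds = read_expression_matrix(paths["expr"], paths["cohorts"])
                gsets = read_gmt(paths["geneset"])
                gset = gsets[0]
                results = []
                for i, cohort in enumerate(ds.cohorts()):
                    res, _ = cohort_deregulation(
                        ds, gset, cohort, n_perm=config.n_perm,
                        seed=seeds["pancancer"] + i,
                    )
                    results.append(res)
                ranked = pancancer_rank(results)
                _write_tsv(
                    record(out / "pancancer_deregulation.tsv"),
                    ["cohort", "rank", "n_set", "n_other", "median_set",
                     "median_other", "log2_fc", "ranksum_p", "perm_p", "n_perm"],
                    [[r.cohort, r.rank, r.n_set, r.n_other,
                      f"{r.median_set:.6g}", f"{r.median_other:.6g}",
                      f"{r.log2_fc:.6g}", f"{r.ranksum_p:.6g}",
                      f"{r.perm_p:.6g}", r.n_perm] for r in ranked],
                )
                write_run_summary(
                    {"stage": "pancancer", "n_cohorts": len(ranked),
                     "top_cohort": ranked[0].cohort,
                     "top_log2_fc": ranked[0].log2_fc,
                     "seed": seeds["pancancer"], "n_perm": config.n_perm},
                    record(out / "pancancer_summary.json"),
                )
                status["pancancer"] = "ok"
            except Exception as exc:  # noqa: BLE001
                status["pancancer"] = "failed"
                warnings.append(f"pancancer: {exc}\n{traceback.format_exc(limit=3)}")
                logger.error("pancancer stage failed: %s", exc)

    # ---- survival ---------------------------------------------------
    if config.stages.get("survival"):
        if dependent_blocked(config.clinical_path is None):
            status["survival"] = "skipped"
            warnings.append("survival: skipped because simulate failed")
        else:
            try:
                tab = read_survival_table(paths["clinical"])
                high, low = stratify_quartiles(tab)
                lr = logrank_test(high, low)
                for name, grp in (("high", high), ("low", low)):
                    km = km_estimate(grp.times, grp.events)
                    _write_tsv(
                        record(out / f"km_{name}.tsv"),
                        ["time", "at_risk", "events", "survival"],
                        [[f"{t:.6g}", int(n), int(d), f"{s:.6g}"]
                         for t, n, d, s in zip(km.event_times, km.at_risk,
                                               km.events, km.survival)],
                    )
                write_run_summary(
                    {"stage": "survival", "chi2": lr.chi2, "p": lr.p,
                     "n_high": len(high), "n_low": len(low),
                     "observed": lr.observed, "expected": lr.expected},
                    record(out / "survival_summary.json"),
                )
                status["survival"] = "ok"
            except Exception as exc:  # noqa: BLE001
                status["survival"] = "failed"
                warnings.append(f"survival: {exc}\n{traceback.format_exc(limit=3)}")
                logger.error("survival stage failed: %s", exc)

    # ---- differential expression -----------------------------------
    if config.stages.get("de"):
        if dependent_blocked(config.de_expr_path is None):
            status["de"] = "skipped"
            warnings.append("de: skipped because simulate failed")
        else:
            try:
                de_path = Path(paths["de_expr"])
                design = de_path.with_name(de_path.stem + "_design.tsv")
                ds = read_expression_matrix(
                    de_path, design if design.exists() else None
                )
                conditions = [c for c in ds.cohorts() if c != config.de_control]
                ctrl = ds.cohort_columns(config.de_control)
                sig_lists: dict[str, set[str]] = {}
                gmt_path = Path(paths["de_expr"]).with_name("target_set.gmt")
                terms = read_gmt(gmt_path) if gmt_path.exists() else (
                    read_gmt(paths["geneset"]) if paths["geneset"] else []
                )
                for cond in conditions:
                    arm = ds.cohort_columns(cond)
                    res = gene_tests(arm, ctrl, ds.gene_ids,
                                     p_threshold=config.bh_alpha,
                                     fc_threshold=config.fc_threshold)
                    _write_tsv(
                        record(out / f"de_{cond}.tsv"),
                        ["gene", "log2_fc", "t_stat", "p", "adj_p", "status"],
                        [[r.gene, f"{r.log2_fc:.6g}", f"{r.t_stat:.6g}",
                          f"{r.p:.6g}", f"{r.adj_p:.6g}", r.status]
                         for r in res],
                    )
                    sig = {r.gene for r in res if r.status != "ns"}
                    sig_lists[cond] = sig
                    if terms:
                        down = {r.gene for r in res if r.status == "down"}
                        enr = hypergeom_enrichment(down, set(ds.gene_ids), terms)
                        _write_tsv(
                            record(out / f"enrichment_{cond}.tsv"),
                            ["term", "k", "K", "n", "N", "p_hyper", "p_bonf"],
                            [[e.term, e.k, e.K, e.n, e.N,
                              f"{e.p_hyper:.6g}", f"{e.p_bonf:.6g}"] for e in enr],
                        )
                if len(sig_lists) >= 2:
                    regions = overlap_sets(sig_lists)
                    _write_tsv(
                        record(out / "de_overlaps.tsv"),
                        ["region", "n_genes"],
                        [["&".join(k), len(v)] for k, v in sorted(regions.items())],
                    )
                status["de"] = "ok"
            except Exception as exc:  # noqa: BLE001
                status["de"] = "failed"
                warnings.append(f"de: {exc}\n{traceback.format_exc(limit=3)}")
                logger.error("de stage failed: %s", exc)

    # ---- assay ------------------------------------------------------
    if config.stages.get("assay"):
        if dependent_blocked(config.dose_response_path is None):
            status["assay"] = "skipped"
            warnings.append("assay: skipped because simulate failed")
        else:
            try:
                import pandas as pd

                dr = pd.read_csv(paths["doseresponse"], sep="\t")
                fit = fit_4pl(dr["dose_uM"], dr["viability_pct"])
                ics = {
                    l: inhibitory_concentration(fit, l) for l in (25, 50, 75)
                } if fit.converged else {}
                ci = bootstrap_ci(
                    dr["dose_uM"], dr["viability_pct"],
                    B=config.bootstrap_B, seed=seeds["doseresponse"],
                ) if fit.converged else {}
                summary = {
                    "stage": "assay",
                    "fit": {"bottom": fit.bottom, "top": fit.top,
                            "hill": fit.hill, "ec50": fit.ec50,
                            "converged": fit.converged},
                    "ic_uM": ics,
                    "ci95": {k: list(v) for k, v in ci.items()},
                }
                if paths["qpcr"]:
                    from .assay_quant import QpcrMeasurement, ddct_fold_change

                    qp = pd.read_csv(paths["qpcr"], sep="\t")
                    folds = {}
                    for gene, sub in qp.groupby("gene"):
                        ctrl = [QpcrMeasurement(r.group, r.gene, r.ct_target, r.ct_reference)
                                for r in sub.itertuples() if r.group == "control"]
                        trt = [QpcrMeasurement(r.group, r.gene, r.ct_target, r.ct_reference)
                               for r in sub.itertuples() if r.group == "treated"]
                        fold, _ = ddct_fold_change(ctrl, trt)
                        folds[gene] = fold
                    summary["qpcr_fold"] = folds
                write_run_summary(summary, record(out / "assay_summary.json"))
                status["assay"] = "ok"
            except Exception as exc:  # noqa: BLE001
                status["assay"] = "failed"
                warnings.append(f"assay: {exc}\n{traceback.format_exc(limit=3)}")
                logger.error("assay stage failed: %s", exc)

    report = RunReport(
        status=status,
        parameters={
            "seed": config.seed, "stage_seeds": seeds, "n_perm": config.n_perm,
            "bh_alpha": config.bh_alpha, "fc_threshold": config.fc_threshold,
            "bonferroni_alpha": config.bonferroni_alpha,
            "bootstrap_B": config.bootstrap_B,
        },
        manifest=manifest,
        wall_clock_s=round(time.monotonic() - t0, 3),
        warnings=warnings,
    )
    report_path = out / "report.json"
    write_run_summary(report.to_dict(), report_path)
    return report
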