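"""End-to-end orchestration: synthetic data -> apical BMD -> gene BMD ->
enrichment -> POD strategies -> D1* -> concordance.

Every stage is optional: a config pointing only at an apical table yields
a report containing only the apical POD.  Runs are deterministic given the
config seed and the report records provenance (config hash, seed,
thresholds) so every number is traceable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import apical as apical_mod
from . import d1 as d1_mod
from . import genebmd, io, pod, synth
from .config import PipelineConfig

log = logging.getLogger("tgxpod")

__all__ = ["run_pipeline"]


def _apical_stage(cfg: PipelineConfig, report: dict) -> None:
    df = io.read_apical(cfg.apical_path)
    summary = apical_mod.apical_pod(df, bmr=cfg.bmr)
    report["apical"] = {
        "bmdl": summary.bmdl, "bmdu": summary.bmdu, "ratio": summary.ratio,
        "per_result": [
            {"family": r.family, "submodel": r.submodel, "series": r.series,
             "bmd": r.bmd, "bmdl": r.bmdl, "bmdu": r.bmdu, "flags": r.flags}
            for r in summary.results],
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages and return the run report (JSON-able)."""
    report: dict = {"provenance": {"config_hash": cfg.config_hash,
                                   "seed": cfg.seed,
                                   "thresholds": {
                                       "bmr": cfg.bmr,
                                       "bmr_sd_units": cfg.bmr_sd_units,
                                       "fit_p_min": cfg.fit_p_min,
                                       "ratio_max": cfg.ratio_max,
                                       "fc_min": cfg.fc_min,
                                       "deg_fc": cfg.deg_fc,
                                       "deg_fdr": cfg.deg_fdr}}}
    matrix = truth = deg = None

    if cfg.apical_path:
        log.info("apical BMD stage: %s", cfg.apical_path)
        _apical_stage(cfg, report)

    if cfg.simulate:
        log.info("synthetic expression stage: %d genes, %.0f%% responsive",
                 cfg.n_genes, 100 * cfg.responsive_fraction)
        design = synth.StudyDesign(doses=cfg.doses, n_per_group=cfg.n_per_group,
                                   seed=cfg.seed)
        matrix, truth = synth.simulate_expression_study(
            design, n_genes=cfg.n_genes,
            responsive_fraction=cfg.responsive_fraction)
        deg = synth.make_deg_table(matrix)
        report["synthetic"] = {"n_genes": cfg.n_genes,
                               "n_responsive": int(truth["responsive"].sum())}
    elif cfg.expression_path and cfg.expression_meta_path:
        matrix = io.read_expression(cfg.expression_path, cfg.expression_meta_path)
    if deg is None and cfg.deg_path:
        deg = io.read_deg_table(cfg.deg_path)

    records = None
    if matrix is not None and deg is not None:
        log.info("gene BMD stage: %d genes", len(matrix.genes))
        from .qc import _linear_fc
        max_fc = _linear_fc(deg).abs().groupby(deg["gene"]).max()
        records = genebmd.gene_bmd_table(
            matrix, max_fc, bmr_sd=cfg.bmr_sd_units,
            fit_p_min=cfg.fit_p_min, ratio_max=cfg.ratio_max, fc_min=cfg.fc_min)
        flags = {c: int((~records[c]).sum()) for c in
                 ("pass_fit_p", "pass_ratio", "pass_range", "pass_fc")}
        report["gene_bmd"] = {"n_fit": len(records),
                              "n_surviving": int(records["survives"].sum()),
                              "n_failing_by_rule": flags}

    estimates = []
    if records is not None and records["survives"].any():
        surv = records[records["survives"]]
        pathway_table = None
        if cfg.gmt_path:
            collection = io.read_gmt(cfg.gmt_path)
            universe = set(records["gene"])
            pathway_table = pod.pathway_pods(
                surv, collection, universe,
                p_max=cfg.enrich_p, min_overlap=cfg.enrich_min_genes)
            report["enrichment"] = {"n_enriched": len(pathway_table)}
        for strat in cfg.strategies:
            try:
                est = pod.aggregate_pod(surv, strat, deg_table=deg,
                                        pathways=pathway_table)
            except (ValueError, KeyError) as exc:
                log.warning("strategy %s skipped: %s", strat, exc)
                continue
            estimates.append(est)
        report["pod_estimates"] = [vars(e) for e in estimates]

    if deg is not None and cfg.k_values:
        log.info("D1* stage: K = %s", list(cfg.k_values))
        d1_results = []
        for k in cfg.k_values:
            try:
                curves = d1_mod.count_degs_by_threshold(deg, [k], cfg.deg_fdr)
                fit = d1_mod.fit_hill_count(curves[float(k)])
                d1_hat = d1_mod.compute_d1(fit)
                star = d1_mod.bootstrap_d1star(fit, n_sim=cfg.n_sim,
                                               seed=cfg.seed)
                d1_results.append({"k": k, "d50": fit.d50, "n": fit.n,
                                   "d1": d1_hat, "d1_star": star})
            except (ValueError, RuntimeError) as exc:
                log.warning("D1 at K=%s skipped: %s", k, exc)
        if d1_results:
            report["d1"] = d1_results

    if estimates and "apical" in report:
        interval = (report["apical"]["bmdl"], report["apical"]["bmdu"])
        conc = pod.concordance_report(estimates, interval)
        report["concordance"] = conc.to_dict(orient="records")

    return report
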