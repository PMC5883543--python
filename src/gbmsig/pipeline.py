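"""End-to-end orchestration: simulate/load -> filter -> select -> validate.

The pipeline chains the discovery procedure: variance filtering and a batch
check, pathway-restricted candidate pooling, quartile-based progression
classes, modified SVM-RFE on the rapid/slow classes, per-gene Cox
coefficients on the held-out intermediate class, prognostic-index risk
stratification, and survival validation (held-out PFS/OS, full-cohort OS,
per-subtype strata, transfer cohort, multivariate independence). A single
global seed fans out to per-stage sub-seeds; the JSON manifest records
seeds, the config hash and per-stage outputs so a run is reproducible
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time as _time
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import cox, io, pathways, preprocess, rfe, simulate, survival

logger = logging.getLogger("gbmsig")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class SimulationSettings(BaseModel):
    n_samples: int = 200
    n_genes: int = 1000
    n_signature_genes: int = 20
    effect_size: float = 1.0
    beta_true: Optional[list[float]] = None
    baseline_hazard: float = 1.0 / 300.0
    censoring_rate: float = 0.3
    n_gene_sets: int = 10
    set_size: int = 25
    batch_count: int = 2
    batch_shift: float = 0.0
    validation_n_samples: int = 120


class RFESettings(BaseModel):
    cost: float = 10.0
    n_folds: int = 5
    elimination_fraction: float = Field(0.10, gt=0.0, lt=1.0)
    ranking: str = "w2"


class PipelineConfig(BaseModel):
    """Validated run configuration (YAML-loadable)."""

    expression_path: Optional[str] = None
    clinical_path: Optional[str] = None
    gmt_path: Optional[str] = None
    simulation: Optional[SimulationSettings] = None

    mad_threshold: float = Field(0.5, ge=0.0)
    gpca_permutations: int = Field(199, ge=99)
    pathway_allowlist: Optional[list[str]] = None
    enrichment_q_cutoff: float = 0.05
    pfs_floor: float = 6.0
    pfs_ceiling: float = 720.0
    rfe: RFESettings = RFESettings()
    risk_strategy: str = "median"
    risk_threshold: Optional[float] = None
    standardize_pi: bool = True
    stratum_column: str = "subtype"
    out_dir: str = "gbmsig_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(x: Any) -> Any:
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    return x


def _comparison_summary(cmp: dict) -> dict:
    lr, hr = cmp["log_rank"], cmp["hazard_ratio"]
    return {
        "median_low": _jsonable(cmp["median_low"]),
        "median_low_ci": [_jsonable(v) for v in cmp["median_low_ci"]],
        "median_high": _jsonable(cmp["median_high"]),
        "median_high_ci": [_jsonable(v) for v in cmp["median_high_ci"]],
        "log_rank_chi_square": lr.chi_square,
        "log_rank_p": lr.p,
        "hazard_ratio": hr.hr,
        "hazard_ratio_p": hr.p_wald,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    t_start = _time.perf_counter()

    def stage(name):
        manifest["stages"].setdefault(name, {})
        logger.info("stage %s starting", name)
        return manifest["stages"][name]

    # ---- inputs -----------------------------------------------------------
    rec = stage("inputs")
    try:
        validation = None
        truth = None
        if config.simulation is not None:
            sim_seed = rfe.derive_seed(config.seed, "simulate")
            sim = config.simulation
            cfg = simulate.SimulationConfig(
                n_samples=sim.n_samples, n_genes=sim.n_genes,
                n_signature_genes=sim.n_signature_genes,
                effect_size=sim.effect_size,
                beta_true=tuple(sim.beta_true) if sim.beta_true else None,
                baseline_hazard=sim.baseline_hazard,
                censoring_rate=sim.censoring_rate,
                n_gene_sets=sim.n_gene_sets, set_size=sim.set_size,
                batch_count=sim.batch_count, batch_shift=sim.batch_shift,
                seed=sim_seed)
            expr, clinical, gene_sets, truth = simulate.simulate_cohort(cfg)
            val_cfg = simulate.SimulationConfig(
                **{**cfg.__dict__,
                   "n_samples": sim.validation_n_samples,
                   "seed": rfe.derive_seed(config.seed, "validation")})
            validation = simulate.simulate_cohort(val_cfg)
            paths = simulate.write_fixture(
                (expr, clinical, gene_sets, truth), out / "inputs")
            rec.update({"mode": "simulate", "seed": sim_seed,
                        "paths": {k: str(v) for k, v in paths.items()}})
        else:
            if not (config.expression_path and config.clinical_path
                    and config.gmt_path):
                raise ValueError(
                    "either simulation settings or all three input paths "
                    "(expression, clinical, GMT) are required")
            expr = io.read_expression(config.expression_path)
            clinical = io.read_clinical(config.clinical_path)
            gene_sets = io.read_gmt(config.gmt_path)
            rec.update({"mode": "load"})
        rec["n_samples"] = int(expr.shape[1])
        rec["n_genes"] = int(expr.shape[0])
    except Exception as exc:
        raise PipelineStageError("inputs", exc) from exc

    # ---- variance filter --------------------------------------------------
    rec = stage("mad_filter")
    try:
        high_var = preprocess.mad_filter(expr, config.mad_threshold)
        if not high_var:
            raise ValueError("no gene passed the MAD filter")
        io.write_gene_list(high_var, out / "high_variance_genes.txt")
        rec.update({"threshold": config.mad_threshold,
                    "n_genes": len(high_var)})
    except Exception as exc:
        raise PipelineStageError("mad_filter", exc) from exc

    # ---- batch-effect check ----------------------------------------------
    rec = stage("gpca_batch_test")
    try:
        batches = clinical.loc[expr.columns, "batch"]
        if batches.nunique() < 2:
            rec.update({"skipped": "single batch"})
        else:
            g = preprocess.gpca_batch_test(
                expr.loc[high_var], batches,
                n_perm=config.gpca_permutations,
                seed=rfe.derive_seed(config.seed, "gpca"))
            io.write_json({"delta": g.delta, "p_perm": g.p_perm,
                           "n_perm": g.n_perm}, out / "batch_effect.json")
            rec.update({"delta": g.delta, "p_perm": g.p_perm})
    except Exception as exc:
        raise PipelineStageError("gpca_batch_test", exc) from exc

    # ---- pathway restriction ----------------------------------------------
    rec = stage("pathway_filter")
    try:
        rows = pathways.enrich(high_var, gene_sets, list(expr.index))
        pd.DataFrame([r.__dict__ for r in rows]).to_csv(
            out / "enrichment.tsv", sep="\t", index=False)
        allowlist = config.pathway_allowlist
        if allowlist is None and truth is not None:
            allowlist = simulate.resistance_set_names(gene_sets)
        chosen = pathways.default_set_choice(
            rows, allowlist=allowlist, q_cutoff=config.enrichment_q_cutoff)
        pool = pathways.select_pathway_genes(rows, chosen, gene_sets, high_var)
        if not pool:
            raise ValueError("pathway-restricted candidate pool is empty")
        io.write_gene_list(pool, out / "candidate_pool.txt")
        rec.update({"n_sets_tested": len(rows), "chosen_sets": chosen,
                    "n_pool_genes": len(pool)})
    except Exception as exc:
        raise PipelineStageError("pathway_filter", exc) from exc

    # ---- progression classes ----------------------------------------------
    rec = stage("progression_classes")
    try:
        classes = preprocess.assign_progression_classes(
            clinical, pfs_floor=config.pfs_floor,
            pfs_ceiling=config.pfs_ceiling)
        rec.update({"q1": classes.q1, "q3": classes.q3,
                    "n_class1": len(classes.class1_ids),
                    "n_class2": len(classes.class2_ids),
                    "n_class3": len(classes.class3_ids)})
    except Exception as exc:
        raise PipelineStageError("progression_classes", exc) from exc

    # ---- feature selection (classes 1 + 2 only) ---------------------------
    rec = stage("feature_selection")
    try:
        train_ids = classes.class1_ids + classes.class2_ids
        labels = pd.Series(
            [1] * len(classes.class1_ids) + [2] * len(classes.class2_ids),
            index=train_ids)
        rfe_cfg = rfe.RFEConfig(
            cost=config.rfe.cost, n_folds=config.rfe.n_folds,
            elimination_fraction=config.rfe.elimination_fraction,
            ranking=config.rfe.ranking,
            seed=rfe.derive_seed(config.seed, "rfe"))
        trace = rfe.run_rfe(expr.loc[pool, train_ids], labels, rfe_cfg)
        signature = rfe.select_signature(trace)
        trace.to_frame().to_csv(out / "rfe_trace.tsv", sep="\t", index=False)
        io.write_json(
            {"steps": [{"n_features": s.n_features,
                        "cv_error": s.cv_error,
                        "feature_ids": list(s.feature_ids)}
                       for s in trace.steps]},
            out / "rfe_trace.json")
        io.write_gene_list(list(signature.gene_ids), out / "signature_genes.txt")
        # held-out discipline: the audit that class 3 never entered selection
        leaked = sorted(set(train_ids) & set(classes.class3_ids))
        rec.update({
            "rfe_samples": sorted(train_ids),
            "heldout_leak": leaked,
            "n_signature_genes": signature.n_genes,
            "cv_error_at_selection": signature.cv_error_at_selection,
        })
        if leaked:
            raise AssertionError(f"held-out samples entered RFE: {leaked}")
    except Exception as exc:
        raise PipelineStageError("feature_selection", exc) from exc

    # ---- prognostic model on the held-out class ---------------------------
    rec = stage("prognostic_model")
    try:
        model = cox.fit_signature_betas(
            expr, clinical.loc[classes.class3_ids],
            list(signature.gene_ids),
            training_cohort_id=f"heldout-class3-{config.config_hash()}")
        model.to_frame().to_csv(out / "signature_model.tsv", sep="\t",
                                index=False)
        pi_heldout = cox.compute_pi(
            expr[classes.class3_ids], model,
            standardize=config.standardize_pi)
        risk_heldout = cox.assign_risk(
            pi_heldout, strategy=config.risk_strategy,
            threshold=config.risk_threshold,
            standardized=config.standardize_pi)
        pd.DataFrame({"sample_id": pi_heldout.index,
                      "pi": pi_heldout.to_numpy(),
                      "group": risk_heldout.group.to_numpy()}).to_csv(
            out / "risk_heldout.tsv", sep="\t", index=False)
        rec.update({"n_training": len(classes.class3_ids),
                    "threshold": risk_heldout.threshold})
    except Exception as exc:
        raise PipelineStageError("prognostic_model", exc) from exc

    # ---- survival validation ----------------------------------------------
    rec = stage("survival")
    try:
        heldout_clin = clinical.loc[classes.class3_ids]
        rec["heldout_pfs"] = _comparison_summary(survival.compare_risk_groups(
            heldout_clin, risk_heldout.group, "pfs_days", "pfs_event"))
        rec["heldout_os"] = _comparison_summary(survival.compare_risk_groups(
            heldout_clin, risk_heldout.group, "os_days", "os_event"))

        pi_all = cox.compute_pi(expr, model, standardize=config.standardize_pi)
        risk_all = cox.assign_risk(
            pi_all, strategy=config.risk_strategy,
            threshold=config.risk_threshold,
            standardized=config.standardize_pi)
        pd.DataFrame({"sample_id": pi_all.index, "pi": pi_all.to_numpy(),
                      "group": risk_all.group.to_numpy()}).to_csv(
            out / "risk_full.tsv", sep="\t", index=False)
        rec["full_os"] = _comparison_summary(survival.compare_risk_groups(
            clinical, risk_all.group, "os_days", "os_event"))

        strata, skipped = survival.stratified_survival(
            clinical, risk_all.group, config.stratum_column,
            "pfs_days", "pfs_event")
        rec["strata_pfs"] = {
            s.stratum: {"log_rank_p": s.log_rank.p,
                        "median_low": _jsonable(s.median_low),
                        "median_high": _jsonable(s.median_high)}
            for s in strata}
        rec["strata_skipped"] = skipped

        if validation is not None:
            v_expr, v_clin, _, _ = validation
            pi_val = cox.transfer_signature(model, v_expr, scaling="z")
            risk_val = cox.assign_risk(pi_val, strategy="median")
            rec["transfer_os"] = _comparison_summary(
                survival.compare_risk_groups(
                    v_clin, risk_val.group, "os_days", "os_event"))
    except Exception as exc:
        raise PipelineStageError("survival", exc) from exc

    # ---- multivariate independence ----------------------------------------
    rec = stage("multivariate")
    try:
        report = survival.multivariate_independence(
            clinical, risk_all.group, "pfs_days", "pfs_event")
        table = []
        for var in report.univariate:
            table.append({
                "variable": var,
                "model": "univariate",
                "hr": report.univariate[var].hr,
                "p_wald": report.univariate[var].p_wald,
            })
            table.append({
                "variable": var,
                "model": "multivariate",
                "hr": report.joint[var].hr,
                "p_wald": report.joint[var].p_wald,
            })
        pd.DataFrame(table).to_csv(out / "multivariate_report.tsv",
                                   sep="\t", index=False)
        rec.update({"n": report.n, "n_events": report.n_events,
                    "joint_p": {v: f.p_wald for v, f in report.joint.items()}})
    except Exception as exc:
        raise PipelineStageError("multivariate", exc) from exc

    logger.info("pipeline done in %.1fs", _time.perf_counter() - t_start)
    io.write_json(manifest, out / "manifest.json")
    return manifest
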