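"""End-to-end orchestration: input -> QC -> scan -> clustering -> RPMM ->
permutation tests -> ridge multinomial, from one config, with optional
stratified re-runs (e.g. postmenopausal samples only).

A run writes a directory of stage subfolders with plain-text artifacts and
a provenance file (config + seed + per-stage counts) sufficient to
reproduce every output.  Identical config + seed gives byte-identical TSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .class_assoc import association_table
from .class_regression import build_design, membership_curves, select_lambda_bic, wald_tests
from .cluster_viz import hcluster, heatmap_export, top_variance_loci
from .datatypes import BetaMatrix
from .io import (
    read_annotation_tsv,
    read_beta_tsv,
    read_covariates_tsv,
    write_beta_tsv,
    write_key_value,
)
from .preprocess import run_qc
from .rpmm import class_profiles, fit_rpmm
from .locus_scan import scan, sign_trend
from .simulate import SimulationConfig, simulate_study, write_study

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("methclass")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Declarative description of one full analysis run."""

    simulation: dict | None = None          # SimulationConfig kwargs
    inputs: dict | None = None              # paths: beta, annotation, covariates, detection_p
    qc: dict = field(default_factory=dict)
    scan_targets: list[str] = field(default_factory=list)
    scan_adjust: list[str] = field(default_factory=list)
    rpmm: dict = field(default_factory=dict)
    permtest_covariates: list[str] | None = None
    permtest_B: int = 10_000
    regression_covariates: list[str] = field(default_factory=list)
    regression_transforms: dict = field(default_factory=dict)
    lambda_grid: list[float] = field(default_factory=lambda: [0.0, 0.5, 1.0, 2.0, 5.0, 10.0])
    referent: object | None = None
    cluster_top_k: int = 750
    cluster_enabled: bool = True
    heatmap_image: bool = False
    stratify: dict | None = None            # {"covariate": ..., "level": ...}
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        def _plain(v):
            if isinstance(v, tuple):
                return [_plain(x) for x in v]
            if isinstance(v, list):
                return [_plain(x) for x in v]
            if isinstance(v, dict):
                return {k: _plain(x) for k, x in v.items()}
            return v

        return {
            "simulation": _plain(self.simulation),
            "inputs": self.inputs,
            "qc": self.qc,
            "scan_targets": list(self.scan_targets),
            "scan_adjust": list(self.scan_adjust),
            "rpmm": self.rpmm,
            "permtest_covariates": self.permtest_covariates,
            "permtest_B": self.permtest_B,
            "regression_covariates": list(self.regression_covariates),
            "regression_transforms": dict(self.regression_transforms),
            "lambda_grid": [float(x) for x in self.lambda_grid],
            "referent": self.referent,
            "cluster_top_k": self.cluster_top_k,
            "cluster_enabled": self.cluster_enabled,
            "heatmap_image": self.heatmap_image,
            "stratify": self.stratify,
            "seed": self.seed,
        }


def _load_inputs(cfg: PipelineConfig, out: Path):
    if cfg.simulation is not None:
        sim_kwargs = dict(cfg.simulation)
        sim_kwargs.setdefault("seed", cfg.seed)
        sim = SimulationConfig(**sim_kwargs)
        study = simulate_study(sim)
        write_study(study, out / "input")
        det = study.signals.detection_p if study.signals is not None else None
        return study.beta, study.annotation, study.covariates, det
    if cfg.inputs is None:
        raise ValueError("config must provide either 'simulation' or 'inputs'")
    beta = read_beta_tsv(cfg.inputs["beta"])
    annotation = read_annotation_tsv(cfg.inputs["annotation"])
    covariates = read_covariates_tsv(cfg.inputs["covariates"])
    det = None
    if cfg.inputs.get("detection_p"):
        det = pd.read_csv(cfg.inputs["detection_p"], sep="\t", index_col=0).T
    return beta, annotation, covariates, det


def _rpmm_stage(beta: BetaMatrix, cfg: PipelineConfig, stage_dir: Path):
    stage_dir.mkdir(parents=True, exist_ok=True)
    model = fit_rpmm(beta, **cfg.rpmm)
    model.W.round(10).to_csv(stage_dir / "membership.tsv", sep="\t", float_format=_FLOAT_FMT)
    model.labels.to_csv(stage_dir / "labels.tsv", sep="\t")
    profiles = class_profiles(model, beta)
    profiles.to_csv(stage_dir / "class_profiles.tsv", sep="\t", float_format=_FLOAT_FMT)
    (stage_dir / "tree.txt").write_text(model.tree_summary() + "\n")
    write_key_value(
        {
            "n_classes": model.n_classes,
            "class_weights": model.class_weights(),
            "class_sizes": model.labels.value_counts().sort_index().to_dict(),
            "splits": model.diagnostics,
        },
        stage_dir / "tree.json",
    )
    return model, profiles


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all configured stages; returns a summary dict (also written
    as provenance.yaml in the run directory)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "config": config.to_dict(), "stages": {}}
    try:
        beta, annotation, covariates, detection = _load_inputs(config, out)
        logger.info("input: %d samples x %d loci", beta.n_samples, beta.n_loci)
        summary["stages"]["input"] = {
            "n_samples": beta.n_samples, "n_loci": beta.n_loci,
        }

        # --- QC ---
        qc_dir = out / "qc"
        qc_dir.mkdir(exist_ok=True)
        beta_qc, report = run_qc(beta, annotation, detection, **config.qc)
        write_beta_tsv(beta_qc, qc_dir / "beta_qc.tsv")
        write_key_value(report.to_dict(), qc_dir / "qc_report.json")
        (qc_dir / "qc_report.txt").write_text(report.summary() + "\n")
        logger.info("qc: %s", report.to_dict())
        summary["stages"]["qc"] = report.to_dict()
        covariates = covariates.loc[beta_qc.sample_ids]

        # --- hierarchical clustering / heatmap ---
        if config.cluster_enabled and beta_qc.n_loci >= 2:
            cl_dir = out / "cluster"
            cl_dir.mkdir(exist_ok=True)
            k = min(config.cluster_top_k, beta_qc.n_loci)
            top = top_variance_loci(beta_qc, k)
            sub = beta_qc.select_loci(top)
            filled = pd.DataFrame(sub.values).apply(lambda c: c.fillna(c.mean()))
            dend_rows = hcluster(filled.to_numpy(), labels=sub.sample_ids)
            dend_cols = hcluster(filled.to_numpy().T, labels=top)
            heatmap_export(
                filled,
                dend_rows.leaf_order.tolist(),
                dend_cols.leaf_order.tolist(),
                image_path=(cl_dir / "heatmap.png") if config.heatmap_image else None,
                tsv_path=cl_dir / "heatmap_ordered.tsv",
            )
            summary["stages"]["cluster"] = {"top_k": k}

        # --- locus scans ---
        if config.scan_targets:
            scan_dir = out / "scan"
            scan_dir.mkdir(exist_ok=True)
            scan_summary = {}
            for target in config.scan_targets:
                res = scan(beta_qc, covariates, target, tuple(config.scan_adjust))
                tbl = res.table.copy()
                tbl.insert(0, "gene", annotation.loc[tbl.index, "gene"])
                tbl.to_csv(scan_dir / f"{target}.tsv", sep="\t", float_format=_FLOAT_FMT)
                trend = sign_trend(res)
                scan_summary[target] = {
                    "pi0": res.pi0,
                    "n_significant_q05": int((res.table["q"] < 0.05).sum()),
                    "n_negative": trend.n_negative,
                    "n_positive": trend.n_positive,
                    "sign_test_p": trend.sign_test_p,
                }
                logger.info("scan %s: %s", target, scan_summary[target])
            write_key_value(scan_summary, scan_dir / "scan_summary.json")
            summary["stages"]["scan"] = scan_summary

        # --- RPMM ---
        model, _ = _rpmm_stage(beta_qc, config, out / "rpmm")
        logger.info("rpmm: %d classes", model.n_classes)
        summary["stages"]["rpmm"] = {
            "n_classes": model.n_classes,
            "class_sizes": model.labels.value_counts().sort_index().to_dict(),
        }

        # --- permutation tests ---
        perm_dir = out / "permtest"
        perm_dir.mkdir(exist_ok=True)
        perm = association_table(
            model.labels, covariates, config.permtest_covariates,
            B=config.permtest_B, seed=config.seed,
        )
        perm.to_csv(perm_dir / "associations.tsv", sep="\t", float_format=_FLOAT_FMT)
        summary["stages"]["permtest"] = {
            "covariates": list(perm.index),
            "min_p": float(perm["perm_p"].min()),
        }

        # --- ridge multinomial regression ---
        if config.regression_covariates and model.n_classes >= 2:
            reg_dir = out / "mlogit"
            reg_dir.mkdir(exist_ok=True)
            design = build_design(
                covariates, config.regression_covariates, config.regression_transforms
            )
            labels = model.labels.loc[design.index]
            lam, fits = select_lambda_bic(
                labels, design, config.lambda_grid, referent=config.referent
            )
            fit = fits[lam]
            fit.coef.to_csv(reg_dir / "coefficients.tsv", sep="\t", float_format=_FLOAT_FMT)
            overall, per_class = wald_tests(fit)
            overall.to_csv(reg_dir / "wald_overall.tsv", sep="\t", float_format=_FLOAT_FMT)
            per_class.to_csv(reg_dir / "wald_per_class.tsv", sep="\t", float_format=_FLOAT_FMT)
            write_key_value(
                {
                    "lambda": lam,
                    "bic_by_lambda": {str(l): f.bic for l, f in fits.items()},
                    "df_eff": fit.df_eff,
                    "referent": str(fit.referent),
                    "n_used": fit.n_used,
                },
                reg_dir / "fit.json",
            )
            summary["stages"]["mlogit"] = {
                "lambda": lam, "referent": str(fit.referent),
                "bic": fit.bic, "df_eff": fit.df_eff,
            }
            logger.info("mlogit: lambda=%s referent=%s", lam, fit.referent)

        # --- stratified re-run (RPMM + permutation tests on a stratum) ---
        if config.stratify:
            covname = config.stratify["covariate"]
            level = config.stratify["level"]
            keep = covariates.index[covariates[covname] == level]
            strat_dir = out / f"stratified_{covname}_{level}"
            beta_s = beta_qc.select_samples([s for s in beta_qc.sample_ids if s in set(keep)])
            logger.info("stratified %s=%s: %d samples", covname, level, beta_s.n_samples)
            model_s, _ = _rpmm_stage(beta_s, config, strat_dir / "rpmm")
            perm_s = association_table(
                model_s.labels, covariates.loc[beta_s.sample_ids],
                config.permtest_covariates, B=config.permtest_B, seed=config.seed,
            )
            perm_s.to_csv(
                strat_dir / "associations.tsv", sep="\t", float_format=_FLOAT_FMT
            )
            summary["stages"]["stratified"] = {
                "covariate": covname, "level": str(level),
                "n_samples": beta_s.n_samples,
                "n_classes": model_s.n_classes,
            }
    except Exception as exc:  # pragma: no cover - error path
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    (out / "provenance.yaml").write_text(yaml.safe_dump(summary, sort_keys=True))
    return summary
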