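"""End-to-end orchestration of the pEMT quantification workflow.

Stages: deconvolve -> score -> refine (stepwise AIC, Ward clustering,
CAF-high exclusion) -> re-score -> survival (univariable screen,
multivariable Cox, 40/40 KM/logrank) -> optional specificity null and
differential expression. Every exclusion decision is logged with the
sample id and reason, and the whole run is summarized in a
machine-readable JSON report that is byte-identical across runs with the
same config and seed (timestamps excluded by design).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .diffexp import consensus_degs, two_group_de
from .deconvolution import deconvolve_cohort
from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSet,
    ValidationError,
    read_clinical_table,
    read_expression_matrix,
    read_gmt,
    read_reference_profile,
)
from .refinement import DEFAULT_CAF_THRESHOLD, refine_cohort
from .scoring import score_cohort
from .specificity import random_geneset_alpha_error
from .survival import (
    cox_multivariable,
    cox_univariable_screen,
    dichotomize_by_quantiles,
    km_logrank,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    expr_path: str
    ref_path: str
    clinical_path: str
    gmt_path: str
    set_name: str | None = None
    expr_scale: str = "linear"
    transform: str = "none"
    log2: bool = True
    caf_threshold: float = DEFAULT_CAF_THRESHOLD
    k_clusters: int = 2
    quantiles: tuple[float, float] = (0.4, 0.6)
    screen_alpha: float = 0.05
    screen_risk_factor_mode: bool = False
    covariates: list[str] = field(default_factory=list)
    run_specificity: bool = False
    specificity_iterations: int = 10_000
    specificity_rule: str = "wald_hr_gt1"
    run_diffexp: bool = False
    de_q_threshold: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "quantiles" in raw:
            raw["quantiles"] = tuple(raw["quantiles"])
        return cls(**raw)

    def validate(self) -> None:
        for stage, p in (
            ("deconvolution", self.ref_path),
            ("scoring", self.gmt_path),
            ("scoring", self.expr_path),
            ("survival", self.clinical_path),
        ):
            if not Path(p).exists():
                raise ValidationError(f"stage {stage!r}: input file not found: {p}")
        lo, hi = self.quantiles
        if not 0 < lo <= hi < 1:
            raise ValidationError("quantiles must satisfy 0 < lower <= upper < 1")
        if not 0 <= self.caf_threshold <= 1:
            raise ValidationError("caf_threshold must be in [0, 1]")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["quantiles"] = list(self.quantiles)
        return d


def _select_gene_set(sets: list[GeneSet], name: str | None) -> GeneSet:
    if name is None:
        return sets[0]
    for gs in sets:
        if gs.name == name:
            return gs
    raise ValidationError(f"gene set {name!r} not in GMT")


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the full workflow; returns (and optionally writes) the report."""
    from . import __version__

    config.validate()
    report: dict = {"version": __version__, "config": config.to_dict(), "stages": {}}
    stage = "load"
    try:
        expr = read_expression_matrix(config.expr_path, scale=config.expr_scale)
        clinical = read_clinical_table(config.clinical_path)
        ref = read_reference_profile(config.ref_path)
        gene_set = _select_gene_set(read_gmt(config.gmt_path), config.set_name)
        report["stages"]["load"] = {
            "n_genes": expr.n_genes,
            "n_samples": expr.n_samples,
            "signature_size": gene_set.m,
        }

        stage = "deconvolve"
        fractions = deconvolve_cohort(expr, ref, transform=config.transform)
        report["stages"]["deconvolve"] = {
            "n_converged": int(fractions.converged.sum()),
            "n_samples": len(fractions.converged),
        }

        stage = "score"
        scores = score_cohort(expr, gene_set, log2_transform=config.log2)
        report["stages"]["score"] = {
            "n_scored": len(scores.sample_ids),
            "mean_score": float(scores.scores.mean()),
        }

        stage = "refine"
        ref_report, retained_expr, rescored = refine_cohort(
            expr,
            scores,
            fractions,
            gene_set,
            caf_threshold=config.caf_threshold,
            k=config.k_clusters,
        )
        for s in ref_report.non_converged_samples:
            logger.info("excluding sample %s: deconvolution did not converge", s)
        for s in ref_report.excluded_samples:
            logger.info("excluding sample %s: member of CAF-high cluster", s)
        report["stages"]["refine"] = ref_report.to_dict()
        report["stages"]["refine"]["n_retained"] = len(ref_report.retained_samples)

        stage = "survival"
        retained = [s for s in ref_report.retained_samples if s in clinical.data.index]
        clin = clinical.subset(retained)
        clin_scores = rescored.scores.loc[retained]
        surv_df = clin.data.copy()
        surv_df["pEMT_score"] = clin_scores
        clin_aug = ClinicalTable(surv_df)
        candidates = ["pEMT_score", *config.covariates]
        screen = cox_univariable_screen(
            clin_aug,
            candidates,
            alpha=config.screen_alpha,
            risk_factor_mode=config.screen_risk_factor_mode,
        )
        relevant = [f.terms[0] for f in screen if bool(f.table["relevant"].iloc[0])]
        screen_report = {
            f.terms[0]: {
                "hr": float(f.table["hr"].iloc[0]),
                "wald_p": float(f.table["wald_p"].iloc[0]),
                "relevant": bool(f.table["relevant"].iloc[0]),
            }
            for f in screen
        }
        multi = cox_multivariable(clin_aug, relevant) if relevant else None
        strat = dichotomize_by_quantiles(clin_scores, *config.quantiles)
        km = km_logrank(clin_aug, strat.groups)
        report["stages"]["survival"] = {
            "screen": screen_report,
            "multivariable": None
            if multi is None
            else {
                "terms": multi.terms,
                "hr": {t: float(v) for t, v in multi.hr.items()},
                "aic": multi.aic,
                "concordance": multi.concordance,
            },
            "logrank_p": km.logrank_p,
            "median_survival": km.median_survival,
            "group_sizes": {g: int((strat.groups == g).sum()) for g in strat.groups.unique()},
        }

        if config.run_specificity:
            stage = "specificity"
            alpha_res = random_geneset_alpha_error(
                retained_expr.subset_samples(retained),
                clin,
                gene_set,
                n_iterations=config.specificity_iterations,
                seed=config.seed,
                rule=config.specificity_rule,
                alpha=config.screen_alpha,
            )
            report["stages"]["specificity"] = alpha_res.to_dict()

        if config.run_diffexp:
            stage = "diffexp"
            de = two_group_de(retained_expr, strat.groups)
            cons = consensus_degs([de], q_threshold=config.de_q_threshold)
            report["stages"]["diffexp"] = {
                "n_significant": int((de.table["q"] <= config.de_q_threshold).sum()),
                "n_consensus": len(cons.genes),
                "n_up": cons.n_up,
                "n_down": cons.n_down,
            }
    except Exception as err:
        report["failed_stage"] = stage
        report["error"] = str(err)
        if out_dir is not None:
            _write_report(report, out_dir)
        raise

    if out_dir is not None:
        _write_report(report, out_dir)
    return report


def _write_report(report: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
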