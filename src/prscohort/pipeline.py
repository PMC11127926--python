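"""End-to-end orchestration: QC -> ancestry -> matching -> scoring ->
association -> skew -> variant tests -> co-occurrence -> survival.

`run_comparison` executes every stage in that order on files the
readers in :mod:`prscohort.io` understand and returns (and optionally
writes) a machine-readable study report. All randomness (control
matching, the Monte-Carlo skew test) is driven by the config seed, so a
rerun with the same config reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ancestry, matching, qc, scoring, stats, survival
from .io import (
    CohortTable,
    GenotypeMatrix,
    read_cohort_table,
    read_genotypes_vcf,
    read_prs_model,
    write_cohort_table,
)

__all__ = ["RunConfig", "run_comparison", "stratify_samples"]

logger = logging.getLogger("prscohort")


@dataclass
class RunConfig:
    case_vcf: str
    control_vcf: str
    phenotypes: str
    model_paths: list[str]
    min_gq: float = 20.0
    min_r2: float = 0.8
    callrate_min: float = 0.90
    hwe_alpha: float = 0.001
    km_q_low: float = 0.10
    km_q_high: float = 0.90
    pca_components: int = 2
    z_threshold: float = 6.0
    drop_ancestry_outliers: bool = True
    match_total: int | None = None
    min_stratum_size: int = 5
    stratify_by: tuple[str, ...] = ("organ_site",)
    skew_n_sim: int = 2000
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.model_paths:
            raise ValueError("at least one PRS model file is required")
        if not (0 < self.callrate_min <= 1):
            raise ValueError("callrate_min must be in (0, 1]")
        if not (0 < self.km_q_low < self.km_q_high < 1):
            raise ValueError("KM quantiles must satisfy 0 < low < high < 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "model_paths" in raw:
            raw["model_paths"] = list(raw["model_paths"])
        if "stratify_by" in raw:
            raw["stratify_by"] = tuple(raw["stratify_by"])
        return cls(**raw)


def stratify_samples(cohort: CohortTable, key: str) -> dict[str, list[str]]:
    """Disjoint, exhaustive partition of samples by a phenotype column.

    ``key`` is typically ``organ_site`` or a treatment/regimen label
    column present in the table; labels are grouped exactly as given.
    """
    if key not in cohort.df.columns:
        raise ValueError(f"unknown stratification key {key!r}")
    out: dict[str, list[str]] = {}
    for label, grp in cohort.df.groupby(key, sort=True):
        out[str(label)] = grp["sample_id"].tolist()
    return out


def _assoc_dict(r: stats.AssociationResult) -> dict:
    return {
        "model": r.model_name,
        "beta": r.beta,
        "se": r.se,
        "or": r.or_,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "p_wald": r.p_wald,
        "n_case": r.n_case,
        "n_control": r.n_control,
    }


def _score_model(model, case_gm, ctrl_gm):
    """Orient both cohorts, impute from controls, score, normalize."""
    combined = GenotypeMatrix(
        sample_ids=case_gm.sample_ids + ctrl_gm.sample_ids,
        variant_keys=list(case_gm.variant_keys),
        dosage=np.vstack([case_gm.dosage, ctrl_gm.dosage]),
    )
    oriented, orient_report = scoring.orient_dosages(combined, model)
    control_mask = np.array(
        [False] * case_gm.n_samples + [True] * ctrl_gm.n_samples
    )
    completed, n_imputed = scoring.impute_missing_dosages(oriented, control_mask)
    result = scoring.compute_prs(completed, model.disease_name, n_imputed)
    n_case = case_gm.n_samples
    case_norm, ctrl_norm = scoring.normalize_scores(
        result.raw_score[:n_case], result.raw_score[n_case:]
    )
    return {
        "oriented": completed,
        "orient_report": orient_report,
        "prs": result,
        "case_norm": case_norm,
        "ctrl_norm": ctrl_norm,
        "control_mask": control_mask,
    }


def score_and_fit(study: dict) -> stats.AssociationResult:
    """Score a simulated study in memory and fit the per-SD odds ratio.

    Convenience for calibration work: orientation, control-mean
    imputation, control-anchored normalization and the logistic fit —
    the same path `run_comparison` takes after QC.
    """
    s = _score_model(
        study["model"], study["case_genotypes"], study["control_genotypes"]
    )
    x = np.concatenate([s["case_norm"], s["ctrl_norm"]])
    y = np.r_[
        np.ones(len(s["case_norm"])), np.zeros(len(s["ctrl_norm"]))
    ].astype(bool)
    return stats.fit_prs_logistic(x, y, study["model"].disease_name)


def run_comparison(config: RunConfig) -> dict:
    """Run the full two-cohort comparison and return the study report."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "models": {}}

    def _stage(name):
        logger.info("stage: %s", name)
        return name

    stage = _stage("read inputs")
    try:
        models = [read_prs_model(p) for p in config.model_paths]
        case_gm = read_genotypes_vcf(config.case_vcf, config.min_gq, config.min_r2)
        ctrl_gm = read_genotypes_vcf(config.control_vcf, config.min_gq, config.min_r2)
        pheno = read_cohort_table(config.phenotypes)

        stage = _stage("shared variants")
        case_gm, ctrl_gm = qc.intersect_shared_variants(case_gm, ctrl_gm)

        stage = _stage("variant QC")
        combined = GenotypeMatrix(
            sample_ids=case_gm.sample_ids + ctrl_gm.sample_ids,
            variant_keys=list(case_gm.variant_keys),
            dosage=np.vstack([case_gm.dosage, ctrl_gm.dosage]),
        )
        _, qc_report = qc.apply_variant_filters(
            combined, config.callrate_min, config.hwe_alpha
        )
        failed = set(qc_report.failed_callrate) | set(qc_report.failed_hwe)
        keep = [j for j, k in enumerate(case_gm.variant_keys) if k not in failed]
        case_gm, ctrl_gm = case_gm.take_variants(keep), ctrl_gm.take_variants(keep)
        report["qc"] = json.loads(qc_report.to_json())

        stage = _stage("ancestry check")
        combined = GenotypeMatrix(
            sample_ids=case_gm.sample_ids + ctrl_gm.sample_ids,
            variant_keys=list(case_gm.variant_keys),
            dosage=np.vstack([case_gm.dosage, ctrl_gm.dosage]),
        )
        pca = ancestry.genotype_pca(combined, k=config.pca_components)
        outliers = ancestry.flag_ancestry_outliers(
            pca, config.pca_components, config.z_threshold
        )
        report["ancestry_outliers"] = outliers
        if config.drop_ancestry_outliers and outliers:
            case_keep = [s for s in case_gm.sample_ids if s not in outliers]
            ctrl_keep = [s for s in ctrl_gm.sample_ids if s not in outliers]
            case_gm = case_gm.take_samples(case_keep)
            ctrl_gm = ctrl_gm.take_samples(ctrl_keep)

        stage = _stage("control matching")
        pheno_case = CohortTable(
            pheno.df[pheno.df["sample_id"].isin(case_gm.sample_ids)]
        )
        pheno_ctrl = CohortTable(
            pheno.df[pheno.df["sample_id"].isin(ctrl_gm.sample_ids)]
        )
        if config.match_total is not None:
            counts = pheno_case.df["organ_site"].value_counts().to_dict()
            plan = matching.allocate_strata(counts, config.match_total)
            matched = matching.sample_matched_controls(plan, pheno_ctrl, config.seed)
            ctrl_gm = ctrl_gm.take_samples(matched.sample_ids)
            pheno_ctrl = matched
            report["match_plan"] = json.loads(plan.to_json())
            if outdir:
                write_cohort_table(matched, outdir / "matched_controls.tsv")

        stage = _stage("scoring and association")
        scored: dict = {}
        for model in models:
            s = _score_model(model, case_gm, ctrl_gm)
            scored[model.disease_name] = s
            x = np.concatenate([s["case_norm"], s["ctrl_norm"]])
            y = np.concatenate(
                [np.ones_like(s["case_norm"]), np.zeros_like(s["ctrl_norm"])]
            )
            assoc = stats.fit_prs_logistic(x, y.astype(bool), model.disease_name)
            entry = {"association": _assoc_dict(assoc)}

            stage = _stage(f"skew: {model.disease_name}")
            entry["skew"] = {}
            for label, vals in (("case", s["case_norm"]), ("control", s["ctrl_norm"])):
                sk = stats.skewness_normality_test(
                    vals, n_sim=config.skew_n_sim, seed=config.seed
                )
                entry["skew"][label] = {
                    "b1": sk.b1, "p": sk.p_value, "n": sk.n, "n_sim": sk.n_sim
                }

            stage = _stage(f"stratified association: {model.disease_name}")
            entry["strata"] = {}
            for key in config.stratify_by:
                if key not in pheno.df.columns:
                    logger.warning("stratification key %r absent; skipped", key)
                    continue
                entry["strata"][key] = {}
                case_strata = stratify_samples(pheno_case, key)
                ctrl_strata = stratify_samples(pheno_ctrl, key)
                case_pos = {sid: i for i, sid in enumerate(case_gm.sample_ids)}
                ctrl_pos = {sid: i for i, sid in enumerate(ctrl_gm.sample_ids)}
                for label in sorted(set(case_strata) & set(ctrl_strata)):
                    ci = [case_pos[sid] for sid in case_strata[label]]
                    ki = [ctrl_pos[sid] for sid in ctrl_strata[label]]
                    if min(len(ci), len(ki)) < config.min_stratum_size:
                        logger.warning(
                            "stratum %s=%s below min size %d; skipped",
                            key, label, config.min_stratum_size,
                        )
                        continue
                    xs = np.concatenate(
                        [s["case_norm"][ci], s["ctrl_norm"][ki]]
                    )
                    ys = np.r_[np.ones(len(ci)), np.zeros(len(ki))].astype(bool)
                    try:
                        sr = stats.fit_prs_logistic(xs, ys, model.disease_name)
                    except ValueError as exc:
                        logger.warning("stratum %s=%s: %s", key, label, exc)
                        continue
                    entry["strata"][key][label] = _assoc_dict(sr)
            report["models"][model.disease_name] = entry

        stage = _stage("variant tests")
        first = scored[models[0].disease_name]
        oriented = first["oriented"]
        n_case = case_gm.n_samples
        results = []
        for j, key in enumerate(oriented.variant_keys):
            r = stats.fisher_allele_test(
                oriented.effect_dosage[:n_case, j],
                oriented.effect_dosage[n_case:, j],
                key,
            )
            results.append(r)
        qvals = stats.bh_adjust([r.fisher_p for r in results])
        report["variant_tests"] = [
            {
                "variant": list(r.variant_key),
                "case_effect": r.case_effect,
                "case_total": r.case_total,
                "control_effect": r.control_effect,
                "control_total": r.control_total,
                "fisher_p": r.fisher_p,
                "bh_q": float(q),
            }
            for r, q in zip(results, qvals)
        ]

        stage = _stage("co-occurrence")
        case_or = scoring.OrientedGenotypes(
            oriented.sample_ids[:n_case], list(oriented.variant_keys),
            oriented.effect_dosage[:n_case], oriented.weights,
        )
        ctrl_or = scoring.OrientedGenotypes(
            oriented.sample_ids[n_case:], list(oriented.variant_keys),
            oriented.effect_dosage[n_case:], oriented.weights,
        )
        diff = stats.cooccurrence_difference(
            stats.carrier_cooccurrence(case_or), stats.carrier_cooccurrence(ctrl_or)
        )
        report["cooccurrence_difference"] = {
            "variants": [list(k) for k in diff.variant_keys],
            "values": diff.values.round(12).tolist(),
        }

        stage = _stage("survival")
        report["survival"] = {}
        known = pheno_ctrl.df["vital_status"] != "missing"
        surv_df = pheno_ctrl.df[known]
        for model in models:
            s = scored[model.disease_name]
            ctrl_ids = ctrl_gm.sample_ids
            scores_by_id = dict(zip(ctrl_ids, s["ctrl_norm"]))
            sub_scores = np.array(
                [scores_by_id[sid] for sid in surv_df["sample_id"]]
            )
            try:
                groups = survival.stratify_by_prs_quantiles(
                    sub_scores, config.km_q_low, config.km_q_high
                )
                lr = survival.logrank_test(
                    surv_df["survival_years"].to_numpy(),
                    (surv_df["vital_status"] == "deceased").to_numpy(),
                    groups,
                    groups=("low", "high"),
                )
                report["survival"][model.disease_name] = {
                    "chi2": lr.chi2,
                    "p": lr.p,
                    "observed": lr.observed,
                    "expected": lr.expected,
                }
            except ValueError as exc:
                logger.warning("survival (%s): %s", model.disease_name, exc)
                report["survival"][model.disease_name] = {"error": str(exc)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if outdir:
        (outdir / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=1) + "\n"
        )
    return report
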