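"""Synthetic two-cohort study generator.

Emulates the statistical structure the comparison pipeline assumes,
without any restricted data: diploid genotypes in Hardy-Weinberg
equilibrium at independent loci, a logistic-liability link between the
raw PRS and case membership with a known odds ratio per score SD, an
optional high-score case subgroup that skews the case distribution,
planted QC failures (imputation R2, call rate, HWE, genotype quality),
organ-site labels matching the case mix of a 51-patient exceptional-
responder registry, and exponential survival with independent
exponential censoring.

All randomness flows from a single master seed through named
substreams, so per-stage draws do not depend on which other stages run.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    CohortTable,
    GenotypeMatrix,
    PRSModel,
    PRSModelVariant,
    write_cohort_table,
    write_genotypes_vcf,
    write_prs_model,
)

__all__ = [
    "ER_REGISTRY_SITE_COUNTS",
    "SimulationConfig",
    "simulate_prs_model",
    "simulate_cohort_genotypes",
    "simulate_survival",
    "plant_qc_failures",
    "simulate_study",
    "write_study_directory",
]

#: Case-cohort organ-site composition used as the default site mix
#: (16 sites, 51 patients; breast-dominated, as in the registry the
#: generator emulates).
ER_REGISTRY_SITE_COUNTS: dict[str, int] = {
    "breast": 13,
    "pancreas": 7,
    "lung": 5,
    "leukemia": 4,
    "ovary": 4,
    "kidney": 3,
    "uterus": 3,
    "brain": 2,
    "intestine": 2,
    "melanoma": 2,
    "bladder": 1,
    "bone": 1,
    "esophagus_or_stomach": 1,
    "gallbladder_or_liver": 1,
    "prostate": 1,
    "thyroid": 1,
}


def _default_site_probs() -> dict[str, float]:
    total = sum(ER_REGISTRY_SITE_COUNTS.values())
    return {s: c / total for s, c in ER_REGISTRY_SITE_COUNTS.items()}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the cohort-comparison setting the pipeline targets:
    51 cases vs 414 matched controls, a 66-variant weight set, and a
    true odds ratio per control-SD of 2.66. Survival defaults encode
    exponential event times with median 12.77 years for cases and 2.89
    years for controls, censored so that roughly 92% / 64% of samples
    are alive at analysis.
    """

    n_case: int = 51
    n_control: int = 414
    n_variants: int = 66
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    weight_sd: float = 0.1
    true_beta: float = math.log(2.66)  # log-OR per pool-SD of raw PRS
    skew_mixture: tuple[float, float] | None = None  # (baseline fraction, +shift in SD)
    missing_rate: float = 0.01
    gq_fail_rate: float = 0.0
    r2_fail_count: int = 0
    highmiss_variant_indices: tuple[int, ...] = ()
    plant_hwe_violation: bool = False
    flip_fraction: float = 0.5  # fraction of variants stored with effect allele as REF
    organ_site_probs: dict[str, float] = field(default_factory=_default_site_probs)
    p_male: float = 0.39
    event_rates: dict[str, float] = field(
        default_factory=lambda: {
            "case": math.log(2) / 12.77,
            "control": math.log(2) / 2.89,
        }
    )
    censor_rates: dict[str, float] = field(
        default_factory=lambda: {"case": 0.62, "control": 0.43}
    )
    pool_size: int | None = None  # default 6 * (n_case + n_control)
    case_oversample: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per cohort")
        lo, hi = self.allele_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("allele_freq_range must lie inside (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.gq_fail_rate < 1:
            raise ValueError("gq_fail_rate must be in [0, 1)")
        tot = sum(self.organ_site_probs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"organ_site_probs sums to {tot}, expected 1")

    @property
    def true_or_per_sd(self) -> float:
        return math.exp(self.true_beta)

    def rngs(self) -> dict[str, np.random.Generator]:
        """Named independent substreams derived from the master seed."""
        names = ("model", "genotypes", "phenotypes", "survival", "qc")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------


def simulate_prs_model(config: SimulationConfig) -> tuple[PRSModel, np.ndarray]:
    """Draw a weight set: frequencies uniform on ``allele_freq_range``,
    weights normal(0, weight_sd). Effect allele is "A", other "G"."""
    if config.n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = config.rngs()["model"]
    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, size=config.n_variants)
    weights = rng.normal(0.0, config.weight_sd, size=config.n_variants)
    variants = [
        PRSModelVariant("1", 1000 * (i + 1), "A", "G", float(w))
        for i, w in enumerate(weights)
    ]
    return PRSModel("synthetic_disease", variants), freqs


def _tilt_theta(freqs, weights, target_shift: float) -> float:
    """Exponential-tilt parameter giving a mean raw-score shift of
    ``target_shift`` (solved by bisection; shift is monotone in theta)."""

    def shift(theta):
        p = freqs * np.exp(theta * weights)
        p = p / (p + (1 - freqs) * np.ones_like(p))
        return float(np.sum(2 * (p - freqs) * weights))

    lo, hi = 0.0, 1.0
    while shift(hi) < target_shift:
        hi *= 2
        if hi > 1e6:
            raise ValueError("requested skew shift unattainable by tilting")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if shift(mid) < target_shift:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort_genotypes(
    model: PRSModel, freqs: np.ndarray, config: SimulationConfig
) -> tuple[GenotypeMatrix, GenotypeMatrix, CohortTable]:
    """Draw case and control genotype matrices plus a phenotype table.

    A pool of HWE genotypes is scored with the model weights; case
    membership is Bernoulli with probability ``expit(alpha + beta z)``
    where ``z`` is the pool-standardized raw score and ``alpha`` is
    calibrated (bisection) so the expected number of cases oversamples
    the requested cohort by ``case_oversample`` — uniform subsampling of
    cases and controls to exact sizes leaves the logistic slope intact.
    With ``skew_mixture=(f, s)`` a fraction ``1 - f`` of the selected
    cases is replaced by genotypes drawn from exponentially tilted
    allele frequencies whose mean raw score sits ``s`` pool-SD higher,
    producing the asymmetric (left-skewed) case score distribution.
    """
    rngs = config.rngs()
    rng = rngs["genotypes"]
    weights = model.weights
    n_var = len(model)
    npool = config.pool_size or 6 * (config.n_case + config.n_control)

    G = rng.binomial(2, freqs, size=(npool, n_var)).astype(float)
    raw = G @ weights
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate pool score (all weights zero?)")
    z = (raw - raw.mean()) / sd

    target_cases = min(config.case_oversample * config.n_case, 0.5 * npool)
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _expit(mid + config.true_beta * z).sum() > target_cases:
            hi = mid
        else:
            lo = mid
    alpha = 0.5 * (lo + hi)
    case_flag = rng.random(npool) < _expit(alpha + config.true_beta * z)
    case_pool = np.flatnonzero(case_flag)
    ctrl_pool = np.flatnonzero(~case_flag)
    if case_pool.size < config.n_case:
        raise ValueError(
            f"pool produced {case_pool.size} cases, need {config.n_case}; "
            "increase pool_size or case_oversample"
        )
    if ctrl_pool.size < config.n_control:
        raise ValueError("pool too small for requested control count")
    case_idx = rng.choice(case_pool, size=config.n_case, replace=False)
    ctrl_idx = rng.choice(ctrl_pool, size=config.n_control, replace=False)
    case_G = G[case_idx].copy()
    ctrl_G = G[ctrl_idx].copy()

    if config.skew_mixture is not None:
        f_base, shift = config.skew_mixture
        if not 0 <= f_base <= 1:
            raise ValueError("skew mixture fraction must be in [0, 1]")
        n_shift = int(round((1.0 - f_base) * config.n_case))
        if n_shift > 0:
            theta = _tilt_theta(freqs, weights, shift * sd)
            p_tilt = freqs * np.exp(theta * weights)
            p_tilt = p_tilt / (p_tilt + (1 - freqs))
            which = rng.choice(config.n_case, size=n_shift, replace=False)
            case_G[which] = rng.binomial(2, p_tilt, size=(n_shift, n_var))

    if config.missing_rate > 0:
        for M in (case_G, ctrl_G):
            mask = rng.random(M.shape) < config.missing_rate
            M[mask] = np.nan

    # VCF encoding: a fraction of variants store the effect allele as REF,
    # so ALT dosage = 2 - effect count and downstream orientation must flip.
    flip = rng.random(n_var) < config.flip_fraction
    keys = []
    for v, fl in zip(model.variants, flip):
        ref, alt = (v.effect_allele, v.other_allele) if fl else (v.other_allele, v.effect_allele)
        keys.append((v.chrom, v.pos, ref, alt))
    case_dos = np.where(flip[None, :], 2.0 - case_G, case_G)
    ctrl_dos = np.where(flip[None, :], 2.0 - ctrl_G, ctrl_G)

    case_ids = [f"case_{i + 1:04d}" for i in range(config.n_case)]
    ctrl_ids = [f"ctrl_{i + 1:04d}" for i in range(config.n_control)]
    case_gm = GenotypeMatrix(case_ids, list(keys), case_dos)
    ctrl_gm = GenotypeMatrix(ctrl_ids, list(keys), ctrl_dos)

    prng = rngs["phenotypes"]
    sites = sorted(config.organ_site_probs)
    probs = np.array([config.organ_site_probs[s] for s in sites])
    import pandas as pd

    rows = []
    for ids, cohort in ((case_ids, "case"), (ctrl_ids, "control")):
        site_draw = prng.choice(sites, size=len(ids), p=probs)
        sex_draw = np.where(prng.random(len(ids)) < config.p_male, "male", "female")
        age_draw = np.clip(prng.normal(64, 9, size=len(ids)).round(), 18, 95)
        for sid, site, sex, age in zip(ids, site_draw, sex_draw, age_draw):
            rows.append((sid, cohort, site, sex, float(age), "missing", np.nan))
    cohort_table = CohortTable(
        pd.DataFrame(
            rows,
            columns=[
                "sample_id",
                "cohort",
                "organ_site",
                "sex",
                "age",
                "vital_status",
                "survival_years",
            ],
        )
    )
    return case_gm, ctrl_gm, cohort_table


def simulate_survival(cohort: CohortTable, config: SimulationConfig) -> CohortTable:
    """Fill vital status and survival years with exponential event times
    and independent exponential censoring, rates per cohort group."""
    for g, r in config.event_rates.items():
        if r <= 0:
            raise ValueError(f"nonpositive event rate for group {g!r}")
    rng = config.rngs()["survival"]
    df = cohort.df.copy()
    event_t = np.empty(len(df))
    censor_t = np.empty(len(df))
    for i, g in enumerate(df["cohort"]):
        event_t[i] = rng.exponential(1.0 / config.event_rates[g])
        c = config.censor_rates.get(g, 0.0)
        censor_t[i] = rng.exponential(1.0 / c) if c > 0 else np.inf
    deceased = event_t <= censor_t
    df["vital_status"] = np.where(deceased, "deceased", "alive")
    df["survival_years"] = np.where(deceased, event_t, censor_t)
    return CohortTable(df)


def plant_qc_failures(matrix: GenotypeMatrix, config: SimulationConfig) -> GenotypeMatrix:
    """Inject known QC failures into a genotype matrix.

    Exactly ``r2_fail_count`` leading variants get an imputation-quality
    annotation of 0.5; each variant listed in
    ``highmiss_variant_indices`` has its missingness raised just above
    10% of samples; with ``plant_hwe_violation`` the last variant's
    genotypes are set all-heterozygous (a gross equilibrium violation).
    """
    n_var, n_samp = matrix.n_variants, matrix.n_samples
    if config.r2_fail_count > n_var:
        raise ValueError("r2_fail_count exceeds variant count")
    if any(i >= n_var for i in config.highmiss_variant_indices):
        raise ValueError("high-missingness variant index out of range")
    rng = config.rngs()["qc"]
    out = matrix.take_variants(range(n_var))
    if config.r2_fail_count > 0:
        r2 = np.full(n_var, np.nan) if out.r2 is None else out.r2
        r2[: config.r2_fail_count] = 0.5
        out.r2 = r2
    for j in config.highmiss_variant_indices:
        n_miss = int(np.floor(0.10 * n_samp)) + 1  # strictly above 10%
        rows = rng.choice(n_samp, size=n_miss, replace=False)
        out.dosage[rows, j] = np.nan
    if config.plant_hwe_violation:
        out.dosage[:, n_var - 1] = 1.0
    return out


# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig) -> dict:
    """One complete synthetic study: model, genotypes, phenotypes."""
    model, freqs = simulate_prs_model(config)
    case_gm, ctrl_gm, cohort = simulate_cohort_genotypes(model, freqs, config)
    cohort = simulate_survival(cohort, config)
    case_gm = plant_qc_failures(case_gm, config)
    ctrl_gm = plant_qc_failures(ctrl_gm, config)
    return {
        "model": model,
        "freqs": freqs,
        "case_genotypes": case_gm,
        "control_genotypes": ctrl_gm,
        "cohort": cohort,
        "config": config,
    }


def write_study_directory(outdir, config: SimulationConfig) -> dict:
    """Emit a complete miniature study: VCF per cohort, PRS model TSV,
    phenotype TSV and a truth JSON. Returns the in-memory study too."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)
    write_prs_model(study["model"], outdir / "model.tsv")
    rng = config.rngs()["qc"]
    for name in ("case", "control"):
        gm = study[f"{name}_genotypes"]
        gq = None
        if config.gq_fail_rate > 0:
            gq = np.where(rng.random(gm.dosage.shape) < config.gq_fail_rate, 15, 99)
        write_genotypes_vcf(gm, outdir / f"{name}.vcf", gq=gq)
    write_cohort_table(study["cohort"], outdir / "phenotypes.tsv")
    truth = dataclasses.asdict(config)
    truth["true_or_per_sd"] = config.true_or_per_sd
    (outdir / "truth.json").write_text(json.dumps(truth, sort_keys=True, default=str))
    return study
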