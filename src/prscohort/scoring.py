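"""PRS scoring: allele orientation, residual-missingness imputation,
the weighted-sum score, and control-anchored normalization.

The score of sample *s* is ``PRS_s = sum_i w_i * X_si`` where ``X_si``
is the sample's effect-allele count at model variant *i* and ``w_i`` the
model weight. VCF dosages count ALT alleles, so each model variant must
first be oriented: when the effect allele is the site's ALT the dosage
is used as-is, when it is the REF the dosage is reflected (2 - ALT
count), and when the model alleles do not match the genotyped alleles
the variant is excluded from scoring.

Normalized scores are expressed in control-cohort standard deviations
around the control mean, so 0 means "the mean score of a typical
(control) sample" and logistic slopes read as log-odds per control SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, PRSModel

__all__ = [
    "OrientedGenotypes",
    "OrientationReport",
    "PRSResult",
    "orient_dosages",
    "impute_missing_dosages",
    "compute_prs",
    "normalize_scores",
]

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class OrientationReport:
    matched: list = field(default_factory=list)  # model keys used as-is
    flipped: list = field(default_factory=list)  # effect allele was REF
    excluded: list = field(default_factory=list)  # allele-set mismatch / absent
    n_palindromic: int = 0


@dataclass
class OrientedGenotypes:
    """Effect-allele dosages aligned with their model weights."""

    sample_ids: list[str]
    variant_keys: list[tuple]  # model keys (chrom, pos, effect, other)
    effect_dosage: np.ndarray  # samples x variants, NaN = missing
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.effect_dosage.shape != (len(self.sample_ids), len(self.variant_keys)):
            raise ValueError("effect dosage dimensions inconsistent")
        if len(self.weights) != len(self.variant_keys):
            raise ValueError("weights not aligned with variants")

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)


def orient_dosages(
    matrix: GenotypeMatrix, model: PRSModel
) -> tuple[OrientedGenotypes, OrientationReport]:
    """Align ALT dosages to the model's effect alleles.

    Variants are matched by (chrom, pos); palindromic (A/T, C/G) sites
    are scored by exact allele match with no strand flipping and counted
    in the report.
    """
    site_index: dict[tuple, list[int]] = {}
    for j, (chrom, pos, _ref, _alt) in enumerate(matrix.variant_keys):
        site_index.setdefault((chrom, pos), []).append(j)

    report = OrientationReport()
    cols, keys, weights = [], [], []
    for v in model.variants:
        chosen = None
        for j in site_index.get((v.chrom, v.pos), []):
            _c, _p, ref, alt = matrix.variant_keys[j]
            if {ref, alt} == {v.effect_allele, v.other_allele}:
                chosen = (j, ref, alt)
                break
        if chosen is None:
            report.excluded.append(v.key)
            continue
        j, ref, alt = chosen
        if frozenset((v.effect_allele, v.other_allele)) in _PALINDROMIC:
            report.n_palindromic += 1
        if v.effect_allele == alt:
            cols.append(matrix.dosage[:, j].copy())
            report.matched.append(v.key)
        else:  # effect allele is REF: reflect the ALT count
            cols.append(2.0 - matrix.dosage[:, j])
            report.flipped.append(v.key)
        keys.append(v.key)
        weights.append(v.weight)

    if not keys:
        raise ValueError(
            f"no variants of model {model.disease_name!r} matched the genotypes"
        )
    oriented = OrientedGenotypes(
        sample_ids=list(matrix.sample_ids),
        variant_keys=keys,
        effect_dosage=np.column_stack(cols),
        weights=np.asarray(weights, dtype=float),
    )
    return oriented, report


def impute_missing_dosages(
    oriented: OrientedGenotypes, control_mask: np.ndarray
) -> tuple[OrientedGenotypes, np.ndarray]:
    """Replace missing effect dosages by the control-cohort mean dosage
    of the variant.

    Returns the completed matrix and the per-sample count of imputed
    entries. Using control means for both cohorts keeps the fill-in
    independent of case status.
    """
    control_mask = np.asarray(control_mask, dtype=bool)
    if control_mask.shape != (len(oriented.sample_ids),):
        raise ValueError("control mask length does not match samples")
    D = oriented.effect_dosage.copy()
    ctrl = D[control_mask, :]
    n_obs = np.sum(~np.isnan(ctrl), axis=0)
    if np.any(n_obs == 0):
        j = int(np.where(n_obs == 0)[0][0])
        raise ValueError(
            f"variant {oriented.variant_keys[j]} entirely missing in controls"
        )
    means = np.nanmean(ctrl, axis=0)
    nan_r, nan_c = np.where(np.isnan(D))
    n_imputed = np.bincount(nan_r, minlength=D.shape[0])
    D[nan_r, nan_c] = means[nan_c]
    completed = OrientedGenotypes(
        sample_ids=list(oriented.sample_ids),
        variant_keys=list(oriented.variant_keys),
        effect_dosage=D,
        weights=oriented.weights.copy(),
    )
    return completed, n_imputed


@dataclass
class PRSResult:
    sample_ids: list[str]
    raw_score: np.ndarray
    model_name: str
    n_variants_used: int
    n_missing_imputed: np.ndarray
    normalized_score: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.raw_score)):
            raise ValueError("raw PRS scores must be finite")


def compute_prs(oriented: OrientedGenotypes, model_name: str = "",
                n_missing_imputed: np.ndarray | None = None) -> PRSResult:
    """Weighted sum of effect-allele dosages per sample."""
    if np.isnan(oriented.effect_dosage).any():
        raise ValueError("effect dosages contain missing values; impute first")
    raw = oriented.effect_dosage @ oriented.weights
    if n_missing_imputed is None:
        n_missing_imputed = np.zeros(len(oriented.sample_ids), dtype=int)
    return PRSResult(
        sample_ids=list(oriented.sample_ids),
        raw_score=raw,
        model_name=model_name,
        n_variants_used=oriented.n_variants,
        n_missing_imputed=np.asarray(n_missing_imputed, dtype=int),
    )


def normalize_scores(
    case_raw: np.ndarray, control_raw: np.ndarray, pooled: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize both cohorts' scores with control mean and SD.

    The control cohort anchors the scale: its normalized scores have
    mean 0 and SD 1 (ddof=1), and a case at 0 sits exactly at the mean
    of typical (control) samples. ``pooled=True`` standardizes with the
    pooled mean/SD instead, for sensitivity analysis.
    """
    case_raw = np.asarray(case_raw, dtype=float)
    control_raw = np.asarray(control_raw, dtype=float)
    ref = np.concatenate([case_raw, control_raw]) if pooled else control_raw
    sd = ref.std(ddof=1)
    if not sd > 0:
        raise ValueError("reference scores are constant; cannot normalize")
    mu = ref.mean()
    return (case_raw - mu) / sd, (control_raw - mu) / sd
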