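"""Variant-level quality control.

Implements the exact Hardy-Weinberg equilibrium test (Levene-Haldane
conditional distribution of the heterozygote count given allele counts),
a call-rate filter, and the cross-cohort shared-variant intersection
applied before any between-cohort scoring.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix

__all__ = [
    "QCReport",
    "hwe_exact_pvalue",
    "apply_variant_filters",
    "intersect_shared_variants",
]


def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value.

    Conditions on the observed allele counts and sums, over every
    heterozygote count compatible with them, the probabilities of the
    configurations no more likely than the observed one (ties included).
    The conditional probability of ``h`` heterozygotes given ``n``
    diploid genotypes and ``nA`` copies of the rarer allele is

        P(h | n, nA) = n! / (nAA! nAa! naa!) * 2^h * nA! na! / (2n)!

    computed here by the standard ratio recurrence in double precision.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be nonnegative integers, got {counts}")
    n_hom_ref, n_het, n_hom_alt = (int(c) for c in counts)
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("all genotype counts are zero")

    n_a = 2 * n_hom_alt + n_het  # copies of one allele
    n_b = 2 * n_hom_ref + n_het
    n_rare = min(n_a, n_b)
    if n_rare == 0:
        return 1.0  # monomorphic: single attainable configuration

    # Heterozygote support: h has the parity of n_rare, 0/1 <= h <= n_rare.
    hs = np.arange(n_rare % 2, n_rare + 1, 2)
    probs = np.empty(hs.size, dtype=float)

    def _ratio_up(h: int) -> float:
        # P(h+2)/P(h) = 4 * n_AA(h) * n_aa(h) / ((h+2)(h+1))
        n_aa = (n_rare - h) // 2
        n_bb = n - n_aa - h
        return 4.0 * n_aa * n_bb / ((h + 2.0) * (h + 1.0))

    # recurse outward from the mode so intermediate values never overflow
    mode = int(np.searchsorted(hs, round(n_a * n_b / (2.0 * n))))
    mode = min(mode, hs.size - 1)
    probs[mode] = 1.0
    for i in range(mode, hs.size - 1):
        probs[i + 1] = probs[i] * _ratio_up(int(hs[i]))
    for i in range(mode, 0, -1):
        probs[i - 1] = probs[i] / _ratio_up(int(hs[i - 1]))
    probs /= probs.sum()

    obs = n_het
    if obs % 2 != n_rare % 2 or obs > n_rare:
        raise ValueError(
            f"heterozygote count {obs} incompatible with allele count {n_rare}"
        )
    p_obs = probs[np.searchsorted(hs, obs)]
    # include configurations with probability <= observed (tiny relative
    # slack so exact ties survive floating-point rounding)
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


@dataclass
class QCReport:
    """Counts and per-filter variant-key lists from variant QC."""

    n_input_variants: int
    n_fail_callrate: int
    n_fail_hwe: int
    n_retained: int
    failed_callrate: list = field(default_factory=list)
    failed_hwe: list = field(default_factory=list)

    def __post_init__(self) -> None:
        failed = set(self.failed_callrate) | set(self.failed_hwe)
        if self.n_retained != self.n_input_variants - len(failed):
            raise ValueError("QCReport counts inconsistent with failed sets")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["failed_callrate"] = [list(k) for k in self.failed_callrate]
        d["failed_hwe"] = [list(k) for k in self.failed_hwe]
        return json.dumps(d, sort_keys=True)


def genotype_counts(dosage_col: np.ndarray) -> tuple[int, int, int]:
    """Observed (hom-ref, het, hom-alt) counts, missing excluded."""
    obs = dosage_col[~np.isnan(dosage_col)]
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


def apply_variant_filters(
    matrix: GenotypeMatrix,
    callrate_min: float = 0.90,
    hwe_alpha: float = 0.001,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove variants with call rate strictly below ``callrate_min`` or
    exact-HWE p-value strictly below ``hwe_alpha``.

    The two rules are evaluated independently on the input matrix (so
    the report reflects each filter on its own) and the retained set is
    the complement of their union; this makes the filters commute.
    """
    if matrix.n_variants == 0 or matrix.n_samples == 0:
        raise ValueError("cannot QC an empty genotype matrix")
    n = matrix.n_samples
    fail_cr, fail_hwe = [], []
    for j, key in enumerate(matrix.variant_keys):
        col = matrix.dosage[:, j]
        n_obs = int(np.sum(~np.isnan(col)))
        if n_obs / n < callrate_min:
            fail_cr.append(key)
        if n_obs > 0:
            if hwe_exact_pvalue(*genotype_counts(col)) < hwe_alpha:
                fail_hwe.append(key)
    failed = set(fail_cr) | set(fail_hwe)
    keep = [j for j, k in enumerate(matrix.variant_keys) if k not in failed]
    report = QCReport(
        n_input_variants=matrix.n_variants,
        n_fail_callrate=len(fail_cr),
        n_fail_hwe=len(fail_hwe),
        n_retained=len(keep),
        failed_callrate=fail_cr,
        failed_hwe=fail_hwe,
    )
    return matrix.take_variants(keep), report


def intersect_shared_variants(
    matrix_a: GenotypeMatrix, matrix_b: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict both cohorts to the variants present in each.

    Only variants shared between the two cohorts enter any downstream
    comparison; the shared set keeps the variant order of ``matrix_a``.
    """
    if matrix_a.n_variants == 0 or matrix_b.n_variants == 0:
        raise ValueError("cannot intersect an empty genotype matrix")
    keys_b = set(matrix_b.variant_keys)
    shared = [k for k in matrix_a.variant_keys if k in keys_b]
    if not shared:
        raise ValueError(
            f"no shared variants between cohorts "
            f"({matrix_a.n_variants} vs {matrix_b.n_variants} variants)"
        )
    idx_a = [matrix_a.variant_keys.index(k) for k in shared]
    pos_b = {k: j for j, k in enumerate(matrix_b.variant_keys)}
    idx_b = [pos_b[k] for k in shared]
    return matrix_a.take_variants(idx_a), matrix_b.take_variants(idx_b)
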