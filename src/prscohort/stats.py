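"""The comparison statistics: per-SD logistic odds ratios with Wald
tests, the sample-skewness statistic with a Monte-Carlo normality test,
exact per-variant allele-frequency tests with BH correction, and
variant carrier co-occurrence matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .scoring import OrientedGenotypes

__all__ = [
    "AssociationResult",
    "SkewResult",
    "VariantTestResult",
    "CooccurrenceMatrix",
    "fit_prs_logistic",
    "sample_skewness",
    "skewness_normality_test",
    "fisher_exact_pvalue",
    "fisher_pvalue_grid",
    "fisher_allele_test",
    "bh_adjust",
    "carrier_cooccurrence",
    "cooccurrence_difference",
]

_Z975 = 1.959963984540054  # two-tailed 95% normal quantile
_SEPARATION_BETA = 15.0  # |slope| beyond this flags complete separation


# ---------------------------------------------------------------------------
# Logistic odds ratio per SD


@dataclass
class AssociationResult:
    """Case-vs-control logistic fit on one normalized PRS."""

    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p_wald: float
    n_case: int
    n_control: int
    model_name: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_ <= self.ci_high):
            raise ValueError("confidence interval does not bracket the OR")
        if not 0 < self.p_wald <= 1:
            raise ValueError("p-value outside (0, 1]")


def fit_prs_logistic(
    scores: np.ndarray, is_case: np.ndarray, model_name: str = ""
) -> AssociationResult:
    """Intercept + slope logistic regression of case membership on the
    normalized score; no covariates.

    The reported odds ratio is per unit of normalized PRS (per control
    SD), with a 95% Wald interval ``exp(beta +/- 1.96 se)`` and a
    two-sided Wald p. Complete separation (diverging slope or failed
    convergence) raises rather than returning a silent estimate.
    """
    scores = np.asarray(scores, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    if scores.shape != is_case.shape:
        raise ValueError("scores and labels differ in length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_case = int(is_case.sum())
    n_control = int((~is_case).sum())
    if n_case == 0 or n_control == 0:
        raise ValueError("both cohorts must be non-empty")
    if scores.std() == 0:
        raise ValueError("zero-variance score; logistic slope undefined")

    X = sm.add_constant(scores)
    try:
        fit = sm.Logit(is_case.astype(float), X).fit(disp=0, maxiter=100)
    except Exception as exc:
        raise ValueError(f"logistic fit failed (separation?): {exc}") from exc
    beta = float(fit.params[1])
    if not fit.mle_retvals.get("converged", True) or abs(beta) > _SEPARATION_BETA:
        raise ValueError(
            f"logistic fit did not converge (slope {beta:.2f}); "
            "scores likely separate the cohorts completely"
        )
    se = float(fit.bse[1])
    z = beta / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return AssociationResult(
        beta=beta,
        se=se,
        or_=math.exp(beta),
        ci_low=math.exp(beta - _Z975 * se),
        ci_high=math.exp(beta + _Z975 * se),
        p_wald=max(p, 5e-324),
        n_case=n_case,
        n_control=n_control,
        model_name=model_name,
    )


# ---------------------------------------------------------------------------
# Skewness


def sample_skewness(values, axis: int = -1):
    """Sample skewness b1 with the mixed-denominator convention:

        b1 = [(1/n) sum (x_i - xbar)^3] / [(1/(n-1)) sum (x_i - xbar)^2]^{3/2}

    (third moment with 1/n, variance with 1/(n-1)). Negative values mean
    a left tail.
    """
    x = np.asarray(values, dtype=float)
    n = x.shape[axis]
    if n < 3:
        raise ValueError("need at least 3 values for skewness")
    d = x - x.mean(axis=axis, keepdims=True)
    s2 = (d**2).sum(axis=axis) / (n - 1)
    if np.any(s2 == 0):
        raise ValueError("constant input; skewness undefined")
    b1 = (d**3).mean(axis=axis) / s2**1.5
    return float(b1) if np.ndim(b1) == 0 else b1


@dataclass
class SkewResult:
    b1: float
    p_value: float
    n: int
    n_sim: int
    seed: int | None

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value outside (0, 1]")


def skewness_normality_test(
    values,
    n_sim: int = 2000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> SkewResult:
    """Monte-Carlo test of normality against skew.

    The null distribution of b1 is simulated by drawing ``n_sim``
    standard-normal samples of the observed size; the add-one estimator

        p = (1 + #{|b1_sim| >= |b1_obs|}) / (n_sim + 1)

    guarantees p >= 1/(n_sim+1). ``alternative`` may be "two-sided",
    "left" (b1_sim <= b1_obs) or "right".
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 values for the normality test")
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000")
    b1_obs = sample_skewness(x)
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_sim, n))
    b1_sim = sample_skewness(sims, axis=1)
    if alternative == "two-sided":
        extreme = np.abs(b1_sim) >= abs(b1_obs)
    elif alternative == "left":
        extreme = b1_sim <= b1_obs
    elif alternative == "right":
        extreme = b1_sim >= b1_obs
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1.0 + int(extreme.sum())) / (n_sim + 1.0)
    return SkewResult(b1=b1_obs, p_value=p, n=n, n_sim=n_sim, seed=seed)


# ---------------------------------------------------------------------------
# Exact allele-frequency tests


def fisher_exact_pvalue(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Rows are allele classes (effect/other), columns cohorts. All
    hypergeometric configurations with the observed margins whose
    probability does not exceed the observed table's are summed; the
    comparison is done on exact integer numerators, so ties are exact
    and no floating-point slack is needed.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n1, n2, m = a + c, b + d, a + b
    if n1 == 0 or n2 == 0:
        raise ValueError("a cohort has zero total alleles")
    lo, hi = max(0, m - n2), min(n1, m)
    num_obs = math.comb(n1, a) * math.comb(n2, b)
    total = 0
    tail = 0
    for k in range(lo, hi + 1):
        num = math.comb(n1, k) * math.comb(n2, m - k)
        total += num
        if num <= num_obs:
            tail += num
    return tail / total


def fisher_pvalue_grid(n1: int, n2: int) -> np.ndarray:
    """Two-sided Fisher p for every table with column totals (n1, n2).

    Entry ``[a, b]`` is the p-value of the table with ``a`` effect
    alleles among ``n1`` case alleles and ``b`` among ``n2`` control
    alleles. Computed with exact integer numerators, one conditional
    diagonal (fixed ``a + b``) at a time.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("margins must be positive")
    comb1 = [math.comb(n1, k) for k in range(n1 + 1)]
    comb2 = [math.comb(n2, k) for k in range(n2 + 1)]
    P = np.empty((n1 + 1, n2 + 1), dtype=float)
    for m in range(n1 + n2 + 1):
        lo, hi = max(0, m - n2), min(n1, m)
        ks = list(range(lo, hi + 1))
        nums = [comb1[k] * comb2[m - k] for k in ks]
        order = sorted(range(len(ks)), key=nums.__getitem__)
        total = sum(nums)
        run = 0
        tail_by_num: dict[int, int] = {}
        for i in order:
            run += nums[i]
            tail_by_num[nums[i]] = run  # rightmost equal keeps the tie sum
        for i, k in enumerate(ks):
            P[k, m - k] = tail_by_num[nums[i]] / total
    return P


@dataclass
class VariantTestResult:
    variant_key: tuple
    case_effect: int
    case_total: int
    control_effect: int
    control_total: int
    fisher_p: float
    bh_q: float | None = None


def _allele_counts(dosage_col: np.ndarray) -> tuple[int, int]:
    obs = dosage_col[~np.isnan(dosage_col)]
    return int(round(obs.sum())), 2 * obs.size


def fisher_allele_test(
    case_dosage: np.ndarray, control_dosage: np.ndarray, variant_key: tuple = ()
) -> VariantTestResult:
    """Compare one variant's effect-allele frequency between cohorts.

    Allele counts are effect-dosage sums over non-missing genotypes with
    totals ``2 x (non-missing samples)``; the test is two-sided Fisher
    on the [effect vs other] x [case vs control] table.
    """
    a, n1 = _allele_counts(np.asarray(case_dosage, dtype=float))
    b, n2 = _allele_counts(np.asarray(control_dosage, dtype=float))
    if n1 == 0 or n2 == 0:
        raise ValueError(f"variant {variant_key}: zero total alleles in a cohort")
    p = fisher_exact_pvalue(a, b, n1 - a, n2 - b)
    return VariantTestResult(
        variant_key=tuple(variant_key),
        case_effect=a,
        case_total=n1,
        control_effect=b,
        control_total=n2,
        fisher_p=p,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to adjust")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Carrier co-occurrence


@dataclass
class CooccurrenceMatrix:
    """Symmetric variant-pair carrier-proportion (or difference) matrix."""

    variant_keys: list[tuple]
    values: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.variant_keys)
        if self.values.shape != (k, k):
            raise ValueError("co-occurrence matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("co-occurrence matrix must be symmetric")


def carrier_cooccurrence(
    oriented: OrientedGenotypes, missing_as_noncarrier: bool = True
) -> CooccurrenceMatrix:
    """Proportion of samples carrying both variants of each pair.

    A sample carries a variant when its effect dosage is >= 1. Missing
    genotypes count as non-carriers (and stay in the denominator) by
    default; ``missing_as_noncarrier=False`` drops samples pairwise.
    """
    D = oriented.effect_dosage
    n = D.shape[0]
    if n == 0:
        raise ValueError("no samples")
    carrier = (D >= 1.0) & ~np.isnan(D)
    if missing_as_noncarrier:
        C = carrier.astype(float)
        values = (C.T @ C) / n
    else:
        obs = (~np.isnan(D)).astype(float)
        C = carrier.astype(float)
        denom = obs.T @ obs
        if np.any(denom == 0):
            raise ValueError("a variant pair has no jointly observed samples")
        values = (C.T @ C) / denom
    return CooccurrenceMatrix(list(oriented.variant_keys), values)


def cooccurrence_difference(
    case: CooccurrenceMatrix, control: CooccurrenceMatrix
) -> CooccurrenceMatrix:
    """Elementwise case-minus-control co-occurrence; positive entries
    mean the pair travels together more often among cases."""
    if case.variant_keys != control.variant_keys:
        raise ValueError("co-occurrence matrices cover different variants")
    return CooccurrenceMatrix(list(case.variant_keys), case.values - control.values)
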