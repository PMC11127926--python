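"""Genotype PCA and ancestry-outlier flagging.

Samples whose genetic background diverges from the bulk of the cohort
distort PRS comparisons (published weight sets transfer poorly across
ancestries), so divergent samples are flagged on the leading principal
components of the dosage matrix and can be excluded upstream of scoring.
The original check was visual; here a robust z-score rule (median/MAD)
makes the exclusion reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .io import GenotypeMatrix

__all__ = ["PCAResult", "genotype_pca", "flag_ancestry_outliers"]

_MAD_SCALE = 1.4826  # MAD -> sigma under normality


@dataclass
class PCAResult:
    sample_ids: list[str]
    scores: np.ndarray  # samples x k
    explained_variance: np.ndarray  # length k, nonincreasing

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.sample_ids), len(self.explained_variance)):
            raise ValueError("PCA score dimensions inconsistent")
        if np.any(np.diff(self.explained_variance) > 1e-9):
            raise ValueError("explained variance must be nonincreasing")


def genotype_pca(matrix: GenotypeMatrix, k: int, scale: bool = False) -> PCAResult:
    """Top-``k`` principal components of the centered dosage matrix.

    Missing dosages are mean-imputed per variant before decomposition
    (this imputation is internal to the ancestry check and separate from
    scoring-time imputation). With ``scale=True`` variants are also
    divided by their standard deviation; zero-variance variants are
    dropped in that case.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    kmax = min(matrix.n_samples - 1, matrix.n_variants)
    if k > kmax:
        raise ValueError(f"k={k} exceeds min(samples-1, variants)={kmax}")
    X = matrix.dosage.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    sd = X.std(axis=0, ddof=0)
    if not np.any(sd > 0):
        raise ValueError("genotype matrix is constant; PCA undefined")
    if scale:
        keep = sd > 0
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAResult(
        sample_ids=list(matrix.sample_ids),
        scores=scores,
        explained_variance=pca.explained_variance_,
    )


def flag_ancestry_outliers(
    pca: PCAResult, n_components: int = 2, z_threshold: float = 6.0
) -> list[str]:
    """Samples whose robust z-score exceeds ``z_threshold`` on any of the
    first ``n_components`` components.

    The robust z is (score - median) / (1.4826 * MAD) per component. A
    zero MAD (more than half the cohort identical on a component) makes
    the rule undefined and raises.
    """
    if n_components > pca.scores.shape[1]:
        raise ValueError("n_components exceeds available components")
    if not z_threshold > 0:
        raise ValueError("z_threshold must be positive")
    S = pca.scores[:, :n_components]
    med = np.median(S, axis=0)
    mad = np.median(np.abs(S - med), axis=0)
    if np.any(mad == 0):
        comp = int(np.where(mad == 0)[0][0]) + 1
        raise ValueError(
            f"MAD is zero on component {comp}; use a raw-distance threshold instead"
        )
    z = np.abs(S - med) / (_MAD_SCALE * mad)
    flagged = np.any(z > z_threshold, axis=1)
    return [s for s, f in zip(pca.sample_ids, flagged) if f]
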