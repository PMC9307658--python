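"""Voxelwise multimodal joint inference.

Per voxel and modality, the association between a subject-level regressor
(rank-based inverse-normal transformed) and the voxel values is summarized by
a product-moment correlation. One sequence of subject permutations (identity
first) is applied synchronously to every voxel and modality, preserving
spatial and cross-modal dependence; per-modality p-values are rank-based
within each voxel/modality permutation distribution with (b + 1)/(P + 1)
counting. The per-voxel combined statistic is Fisher's

    F = -2 * sum_k ln(p_k)

over the K modalities, and family-wise error is controlled through the
permutation distribution of the maximum combined statistic over voxels.

Also provided: Spearman correlation for reporting, and a Steiger-style paired
comparison of two dependent correlations sharing a common variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .datasets import SkeletonDataset

__all__ = [
    "inverse_normal_transform",
    "fisher_combine",
    "modality_pvalues",
    "JointInference",
    "permutation_fwe",
    "spearman_correlation",
    "compare_dependent_correlations",
    "CorrelationComparison",
]


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal (Blom) transform.

    Maps value i to the standard-normal quantile of
    ``(rank_i - 3/8) / (n + 1/4)`` with average ranks for ties; preserves the
    rank order of the input.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("inverse_normal_transform requires a 1-D array with n >= 2")
    # a fully tied input maps to all average ranks, i.e. all zeros; rejecting
    # a constant *regressor* is the caller's concern (see JointInference.fit)
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.375) / (len(values) + 0.25))


def fisher_combine(p_values) -> float:
    """Fisher's combining function, ``-2 * sum(ln p_k)``."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(-2.0 * np.log(p).sum())


def _blom_columns(values: np.ndarray) -> np.ndarray:
    """Blom transform applied to each column of a 2-D array."""
    ranks = stats.rankdata(values, method="average", axis=0)
    return stats.norm.ppf((ranks - 0.375) / (values.shape[0] + 0.25))


def _permutation_statistics(
    data: np.ndarray,
    regressor: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlation statistics for identity + permutations.

    Returns ``(stats, constant)`` where ``stats`` has shape
    ``(n_permutations + 1, n_columns)`` (row 0 = identity) and ``constant``
    flags zero-variance columns (statistic forced to 0).
    """
    n = data.shape[0]
    z = (regressor - regressor.mean()) / regressor.std()
    col_sd = data.std(axis=0)
    constant = col_sd == 0
    centered = data - data.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(constant, 0.0, centered / np.where(constant, 1.0, col_sd))
    perms = np.empty((n_permutations + 1, n))
    perms[0] = z
    for i in range(1, n_permutations + 1):
        perms[i] = z[rng.permutation(n)]
    return perms @ scaled / n, constant


def _rank_pvalues(statistics: np.ndarray) -> np.ndarray:
    """(b + 1)/(P + 1)-style p-values of every row within its own column's
    permutation distribution (identity included in the pool)."""
    total = statistics.shape[0]
    rank_min = stats.rankdata(statistics, method="min", axis=0)
    return (total + 1 - rank_min) / total


def _directional(statistics: np.ndarray, direction: str) -> np.ndarray:
    if direction == "negative":
        return -statistics
    if direction == "positive":
        return statistics
    if direction == "two-sided":
        return np.abs(statistics)
    raise ValueError("direction must be 'negative', 'positive' or 'two-sided'")


def modality_pvalues(
    skeleton,
    regressor,
    n_permutations: int = 1000,
    direction: str = "negative",
    seed=None,
    transform_voxels: bool = False,
    full: bool = False,
):
    """Per-voxel, per-modality permutation p-values.

    The regressor is Blom-transformed if not already; the same permutation
    sequence (identity as permutation 0) is applied synchronously to all
    voxels and modalities. With ``full=True`` returns the whole
    ``(P + 1, n_voxels, K)`` permutation representation; otherwise the
    observed ``(n_voxels, K)`` p-values.
    """
    values = skeleton.values if isinstance(skeleton, SkeletonDataset) else np.asarray(skeleton)
    n, v, k = values.shape
    reg = np.asarray(regressor, dtype=float)
    if len(reg) != n:
        raise ValueError("regressor length does not match n_subjects")
    z = inverse_normal_transform(reg)
    data = values.reshape(n, v * k)
    if transform_voxels:
        data = _blom_columns(data)
    rng = np.random.default_rng(seed)
    statistics, constant = _permutation_statistics(data, z, n_permutations, rng)
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant voxel/modality columns; p set to 1")
    p = _rank_pvalues(_directional(statistics, direction))
    p[:, constant] = 1.0
    p = p.reshape(-1, v, k)
    return p if full else p[0]


@dataclass
class JointInferenceResult:
    fisher_stat: np.ndarray
    modality_p: np.ndarray
    combined_p: np.ndarray
    fwe_p: np.ndarray
    significant_mask: np.ndarray
    n_permutations: int
    seed: int | None
    direction: str
    max_stat_distribution: np.ndarray


class JointInference(BaseEstimator):
    """Voxelwise Fisher-combination permutation test with max-statistic FWE.

    Parameters
    ----------
    n_permutations : int
        Number of subject permutations (identity excluded from the count but
        included in every p-value denominator, so the minimum attainable p is
        ``1 / (n_permutations + 1)``).
    direction : {'negative', 'positive', 'two-sided'}
        Sidedness of the per-modality p-values before combination. The
        default tests for concordant negative association (more myelin-like
        marker values with smaller inhibition ratios).
    alpha : float
        Family-wise significance level for ``significant_mask_``.
    transform_voxels : bool
        Also Blom-transform every voxel/modality column, making the statistic
        fully rank-based (invariant to monotone rescaling of a modality).
    random_state : int or None
        Seed of the permutation sequence.

    Attributes (after ``fit``)
    --------------------------
    fisher_stat_ : (n_voxels,) observed combined statistic.
    modality_p_ : (n_voxels, K) observed per-modality permutation p-values.
    combined_p_ : (n_voxels,) uncorrected p of the combined statistic.
    fwe_p_ : (n_voxels,) FWE-corrected p via the max-statistic distribution.
    significant_mask_ : (n_voxels,) boolean, ``fwe_p_ <= alpha``.
    """

    def __init__(
        self,
        n_permutations: int = 1000,
        direction: str = "negative",
        alpha: float = 0.05,
        transform_voxels: bool = False,
        random_state: int | None = None,
    ):
        self.n_permutations = n_permutations
        self.direction = direction
        self.alpha = alpha
        self.transform_voxels = transform_voxels
        self.random_state = random_state

    def fit(self, X, y):
        """Run the joint inference of voxel data ``X`` against regressor ``y``.

        ``X`` is a SkeletonDataset or an (n_subjects, n_voxels, K) array; ``y``
        the per-subject scalar regressor (raw scale; Blom-transformed
        internally).
        """
        values = X.values if isinstance(X, SkeletonDataset) else np.asarray(X, dtype=float)
        if values.ndim != 3:
            raise ValueError("X must be (n_subjects, n_voxels, n_modalities)")
        n, v, k = values.shape
        if n < 6:
            raise ValueError(f"joint inference requires at least 6 subjects, got {n}")
        y = np.asarray(y, dtype=float)
        if len(y) != n:
            raise ValueError("regressor length does not match n_subjects")
        if np.all(y == y[0]):
            raise ValueError("regressor is constant; inference is undefined")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

        p_all = modality_pvalues(
            values,
            y,
            n_permutations=self.n_permutations,
            direction=self.direction,
            seed=self.random_state,
            transform_voxels=self.transform_voxels,
            full=True,
        )
        total = p_all.shape[0]
        fisher = -2.0 * np.log(p_all).sum(axis=2)       # (P + 1, n_voxels)
        max_stat = fisher.max(axis=1)
        observed = fisher[0]
        self.fisher_stat_ = observed
        self.modality_p_ = p_all[0]
        self.combined_p_ = (fisher >= observed[None, :]).sum(axis=0) / total
        self.fwe_p_ = (max_stat[:, None] >= observed[None, :]).sum(axis=0) / total
        self.significant_mask_ = self.fwe_p_ <= self.alpha
        self.max_stat_distribution_ = max_stat
        self.n_voxels_ = v
        self.n_modalities_ = k
        return self

    def result(self) -> JointInferenceResult:
        return JointInferenceResult(
            fisher_stat=self.fisher_stat_,
            modality_p=self.modality_p_,
            combined_p=self.combined_p_,
            fwe_p=self.fwe_p_,
            significant_mask=self.significant_mask_,
            n_permutations=self.n_permutations,
            seed=self.random_state,
            direction=self.direction,
            max_stat_distribution=self.max_stat_distribution_,
        )


def permutation_fwe(
    skeleton,
    regressor,
    n_permutations: int = 1000,
    seed: int | None = None,
    direction: str = "negative",
    alpha: float = 0.05,
    transform_voxels: bool = False,
) -> JointInferenceResult:
    """Functional wrapper over :class:`JointInference`."""
    est = JointInference(
        n_permutations=n_permutations,
        direction=direction,
        alpha=alpha,
        transform_voxels=transform_voxels,
        random_state=seed,
    )
    return est.fit(skeleton, regressor).result()


def significant_clusters(mask: np.ndarray) -> list[np.ndarray]:
    """Connected components (runs) of a 1-D significance mask, for reporting."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    return np.split(idx, breaks)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman_correlation requires paired samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationComparison:
    r_common_vs_a: float
    r_common_vs_b: float
    r_a_vs_b: float
    n: int
    z: float
    p: float


def compare_dependent_correlations(
    r_common_a: float, r_common_b: float, r_ab: float, n: int
) -> CorrelationComparison:
    """Steiger test for two overlapping dependent correlations.

    Compares corr(common, A) with corr(common, B) measured on the same ``n``
    subjects, accounting for the dependence through corr(A, B), using Fisher
    z-transformed coefficients and the back-transformed mean correlation
    (Steiger's Z-bar-star).
    """
    if n < 4:
        raise ValueError("n must be at least 4")
    for r in (r_common_a, r_common_b, r_ab):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    z1 = np.arctanh(r_common_a)
    z2 = np.arctanh(r_common_b)
    rbar = (r_common_a + r_common_b) / 2.0
    num = r_ab * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_ab**2)
    cov = num / (1 - rbar**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - cov)))
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationComparison(
        r_common_vs_a=r_common_a,
        r_common_vs_b=r_common_b,
        r_a_vs_b=r_ab,
        n=n,
        z=float(z),
        p=float(min(p, 1.0)),
    )
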