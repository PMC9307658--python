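"""PCA myelin composite over significant voxels.

For each subject, the mean of every modality over the masked voxels yields a
subjects-by-modalities matrix; columns are standardized and the first
principal component of their correlation structure serves as a single
subject-level myelin score. The component is oriented so that a higher score
means more myelin-like marker values (positive correlation with the
across-modality mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datasets import SkeletonDataset


@dataclass
class CompositeScores:
    scores: np.ndarray
    variance_explained: float
    loadings: np.ndarray
    modality_names: tuple[str, ...]
    mask_size: int


class MyelinComposite(BaseEstimator, TransformerMixin):
    """First principal component of standardized per-modality means.

    Fit on an ``(n_subjects, K)`` matrix of modality means (see
    :func:`modality_means`); ``transform`` returns the per-subject
    first-component scores (zero mean by construction).

    Attributes (after ``fit``)
    --------------------------
    loadings_ : (K,) first-component loadings on the standardized modalities.
    variance_explained_ : proportion of total variance carried by the
        component.
    kept_ : boolean mask of modalities retained (constant columns dropped).
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_subjects, n_modalities)")
        n, k = X.shape
        if n < 3:
            raise ValueError("composite extraction requires at least 3 subjects")
        sd = X.std(axis=0)
        kept = sd > 0
        if (~kept).any():
            warnings.warn(f"dropping {int((~kept).sum())} constant modality column(s)")
        if kept.sum() == 0:
            raise ValueError("all modality columns are constant")
        z = (X[:, kept] - X[:, kept].mean(axis=0)) / sd[kept]
        # PCA of the correlation structure via SVD of the standardized matrix
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        loadings = vt[0]
        scores = z @ loadings
        # orientation: higher score = higher across-modality mean
        if np.corrcoef(scores, z.mean(axis=1))[0, 1] < 0:
            loadings = -loadings
        self.mean_ = X[:, kept].mean(axis=0)
        self.scale_ = sd[kept]
        self.kept_ = kept
        self.loadings_ = loadings
        self.variance_explained_ = float(s[0] ** 2 / (s**2).sum())
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        z = (X[:, self.kept_] - self.mean_) / self.scale_
        return z @ self.loadings_


def modality_means(skeleton: SkeletonDataset, mask) -> np.ndarray:
    """Per-subject mean of each modality over the masked voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (skeleton.n_voxels,):
        raise ValueError("mask length does not match n_voxels")
    if not mask.any():
        raise ValueError("mask selects no voxels")
    return skeleton.values[:, mask, :].mean(axis=1)


def extract_composite(skeleton: SkeletonDataset, mask) -> CompositeScores:
    """Extract the first-PC myelin composite from the masked voxels."""
    means = modality_means(skeleton, mask)
    pca = MyelinComposite().fit(means)
    kept_names = tuple(
        name for name, keep in zip(skeleton.modality_names, pca.kept_) if keep
    )
    return CompositeScores(
        scores=pca.transform(means),
        variance_explained=pca.variance_explained_,
        loadings=pca.loadings_,
        modality_names=kept_names,
        mask_size=int(np.asarray(mask, dtype=bool).sum()),
    )
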