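"""Feature representations: Histogram, Histogram+PCA, Histogram+PCA+BoW.

Concatenated descriptor histograms are either used directly, reduced
with PCA (defaults: 40 components for HoG, 20 for LBP), or further
encoded per volume as a bag of visual words: a k-means codebook is
learned on training B-scan vectors and each volume becomes the
histogram of nearest-word assignments of its B-scans.

Within cross-validation both PCA and the codebook are fitted on
training-fold data only.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


class HistogramPCA(BaseEstimator, TransformerMixin):
    """PCA reduction of concatenated descriptor histograms.

    Thin wrapper around :class:`sklearn.decomposition.PCA` that fixes
    component signs (largest-magnitude loading positive) for
    deterministic output, and clamps ``n_components`` to
    ``n_samples - 1`` at small sample sizes (logged).
    """

    def __init__(self, n_components: int = 20, seed: int = 0):
        self.n_components = n_components
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = min(self.n_components, X.shape[1])
        if n > X.shape[0]:
            raise ValueError(
                f"n_components={self.n_components} exceeds n_samples={X.shape[0]}"
            )
        if n == X.shape[0]:
            n = X.shape[0] - 1
            logger.warning("PCA components clamped to n_samples - 1 = %d", n)
        pca = PCA(n_components=n, svd_solver="full", random_state=self.seed)
        pca.fit(X)
        comps = pca.components_.copy()
        flip = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
        comps *= flip[:, None]
        self.mean_ = pca.mean_
        self.components_ = comps
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.n_components_ = n
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean_.shape[0]:
            raise ValueError(f"dim mismatch: {X.shape[1]} vs fitted {self.mean_.shape[0]}")
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, Z) -> np.ndarray:
        return np.asarray(Z) @ self.components_ + self.mean_


def fit_pca(train: np.ndarray, n_components: int, seed: int = 0) -> HistogramPCA:
    return HistogramPCA(n_components=n_components, seed=seed).fit(train)


def transform_pca(model: HistogramPCA, X: np.ndarray) -> np.ndarray:
    return model.transform(X)


class BagOfWords(BaseEstimator, TransformerMixin):
    """k-means visual-word codebook over B-scan vectors.

    ``fit`` learns ``n_words`` centroids (k-means++ init, 10 restarts,
    tol 1e-6, max 300 iterations); ``transform`` maps a list of
    per-volume B-scan matrices to occurrence histograms whose counts
    sum to each volume's B-scan count.
    """

    def __init__(self, n_words: int = 30, seed: int = 0):
        self.n_words = n_words
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.n_words < 2:
            raise ValueError("n_words must be >= 2")
        if X.shape[0] < self.n_words:
            raise ValueError(f"need >= {self.n_words} samples to fit the codebook")
        km = KMeans(
            n_clusters=self.n_words,
            init="k-means++",
            n_init=10,
            tol=1e-6,
            max_iter=300,
            random_state=self.seed,
        ).fit(X)
        self.centroids_ = km.cluster_centers_
        self.inertia_ = float(km.inertia_)
        return self

    def encode(self, vectors: np.ndarray) -> np.ndarray:
        """Occurrence histogram of nearest-centroid assignments (ties -> lowest index)."""
        vectors = np.asarray(vectors, dtype=float)
        if vectors.ndim != 2 or vectors.shape[1] != self.centroids_.shape[1]:
            raise ValueError("B-scan vectors do not match codebook dimensionality")
        d2 = ((vectors[:, None, :] - self.centroids_[None]) ** 2).sum(axis=-1)
        words = np.argmin(d2, axis=1)
        return np.bincount(words, minlength=self.n_words).astype(float)

    def transform(self, volumes) -> np.ndarray:
        return np.stack([self.encode(v) for v in volumes])


def fit_codebook(train: np.ndarray, n_words: int, seed: int = 0) -> BagOfWords:
    return BagOfWords(n_words=n_words, seed=seed).fit(train)


def encode_volume(codebook: BagOfWords, vectors: np.ndarray) -> np.ndarray:
    return codebook.encode(vectors)
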