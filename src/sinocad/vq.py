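"""Local-intensity feature vectors, Karhunen-Loeve reduction and online VQ.

These are the building blocks of the hierarchical vector-quantization
candidate detector: every interior voxel of a region contributes a
7-element vector (its own intensity plus the six face neighbours), the
vectors are reduced by a KL/PCA transform keeping at least 95% of the
variance, and a self-adaptive online VQ clusters them into tissue classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .core import CTVolume

#: order of the 7 components: centre, z-1, z+1, y-1, y+1, x-1, x+1
NEIGHBOR_ORDER = ("center", "z-", "z+", "y-", "y+", "x-", "x+")


@dataclass
class FeatureVectorSet:
    """Per-voxel feature vectors with their source voxel coordinates."""

    vectors: np.ndarray       # (N, d)
    voxel_index: np.ndarray   # (N, 3) int, (z, y, x)
    retained_dims: int

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be an (N, d) matrix")
        if len(self.vectors) != len(self.voxel_index):
            raise ValueError("one vector per voxel required")
        if not (1 <= self.retained_dims <= 7):
            raise ValueError("retained_dims must lie in 1..7")


def extract_feature_vectors(volume: CTVolume | np.ndarray,
                            region_mask: np.ndarray) -> FeatureVectorSet:
    """First-order 3-D neighbourhood vectors for every voxel in a region.

    Component order is ``NEIGHBOR_ORDER`` (centre first, then the two z,
    y and x face neighbours).  Voxels on the volume border use
    replicate-edge padding so every region voxel yields a full 7-vector.
    """
    vol = volume.intensities if isinstance(volume, CTVolume) else np.asarray(volume, float)
    region_mask = np.asarray(region_mask, bool)
    if region_mask.shape != vol.shape:
        raise ValueError("region_mask must have the same shape as the volume")
    if not region_mask.any():
        raise ValueError("region_mask is empty")
    p = np.pad(vol, 1, mode="edge")
    shifts = [
        p[1:-1, 1:-1, 1:-1],   # center
        p[:-2, 1:-1, 1:-1],    # z-
        p[2:, 1:-1, 1:-1],     # z+
        p[1:-1, :-2, 1:-1],    # y-
        p[1:-1, 2:, 1:-1],     # y+
        p[1:-1, 1:-1, :-2],    # x-
        p[1:-1, 1:-1, 2:],     # x+
    ]
    vectors = np.stack([s[region_mask] for s in shifts], axis=1)
    voxel_index = np.argwhere(region_mask)
    return FeatureVectorSet(vectors, voxel_index, retained_dims=7)


class KLReduce(BaseEstimator, TransformerMixin):
    """Karhunen-Loeve (PCA) reduction keeping a variance fraction.

    Projects feature vectors onto the smallest leading set of principal
    components whose eigenvalues sum to at least ``variance_threshold`` of
    the total variance.  Zero total variance degenerates to one dimension.
    """

    def __init__(self, variance_threshold: float = 0.95):
        self.variance_threshold = variance_threshold

    def fit(self, X: np.ndarray, y=None) -> "KLReduce":
        X = np.asarray(X, dtype=np.float64)
        if len(X) < 2:
            raise ValueError("need at least 2 vectors for the KL transform")
        if not (0.0 < self.variance_threshold <= 1.0):
            raise ValueError("variance_threshold must lie in (0, 1]")
        self.pca_ = PCA(n_components=None, svd_solver="full").fit(X)
        ratios = self.pca_.explained_variance_ratio_
        total = self.pca_.explained_variance_.sum()
        if total <= 1e-12:
            self.n_components_ = 1
        else:
            csum = np.cumsum(ratios)
            self.n_components_ = int(np.searchsorted(csum, self.variance_threshold - 1e-12) + 1)
            self.n_components_ = min(self.n_components_, X.shape[1])
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "pca_")
        return self.pca_.transform(np.asarray(X, dtype=np.float64))[:, : self.n_components_]

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "pca_")
        full = np.zeros((len(Z), self.pca_.n_components_))
        full[:, : self.n_components_] = Z
        return self.pca_.inverse_transform(full)


def kl_reduce(features: FeatureVectorSet,
              variance_threshold: float = 0.95) -> tuple[FeatureVectorSet, KLReduce]:
    """Functional wrapper: reduce a feature set, returning it with the fitted transform."""
    red = KLReduce(variance_threshold).fit(features.vectors)
    Z = red.transform(features.vectors)
    return FeatureVectorSet(Z, features.voxel_index, retained_dims=red.n_components_), red


@dataclass
class VQModel:
    """A learned codebook with its training metadata."""

    codebook: np.ndarray
    class_count: int
    learning_schedule: str
    iteration_count: int


class OnlineVQ(BaseEstimator, ClusterMixin):
    """Self-adaptive online vector quantization (competitive learning).

    Codebook vectors are initialised at quantiles of the first principal
    component and updated by winner-take-all moves with a decaying
    learning rate ``eta_t = eta0 / (1 + t / tau)`` (t counts samples
    seen).  Samples are processed in small aggregation chunks so that the
    winner search is vectorised; passes repeat until the codebook moves
    less than ``tol`` between passes.  After fitting, classes are
    relabelled in ascending order of codebook component mean, so class 0
    is always the lowest-intensity class.
    """

    def __init__(self, n_classes: int = 2, eta0: float = 0.2, tau: float | None = None,
                 tol: float = 1e-4, max_passes: int = 8, chunk_size: int = 1024,
                 random_state: int = 0):
        self.n_classes = n_classes
        self.eta0 = eta0
        self.tau = tau
        self.tol = tol
        self.max_passes = max_passes
        self.chunk_size = chunk_size
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "OnlineVQ":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be (N, d)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        n_distinct = len(np.unique(X, axis=0))
        if n_distinct < self.n_classes:
            raise ValueError(
                f"only {n_distinct} distinct vectors for {self.n_classes} classes "
                f"({self.n_classes - n_distinct} short)")
        rng = np.random.default_rng(self.random_state)
        n, d = X.shape
        tau = self.tau if self.tau is not None else max(n / 2.0, 1.0)

        # initialise at quantiles of the first principal component
        centred = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        score = centred @ vt[0]
        order = np.argsort(score, kind="stable")
        qpos = ((np.arange(self.n_classes) + 0.5) / self.n_classes * (n - 1)).astype(int)
        code = X[order[qpos]].copy()
        # quantile picks can coincide on heavily quantised data; nudge apart
        for k in range(1, self.n_classes):
            while any(np.allclose(code[k], code[j]) for j in range(k)):
                code[k] = X[rng.integers(n)]

        t_seen = 0
        passes = 0
        for _ in range(self.max_passes):
            passes += 1
            prev = code.copy()
            perm = rng.permutation(n)
            for i in range(0, n, self.chunk_size):
                chunk = X[perm[i:i + self.chunk_size]]
                win = cdist(chunk, code).argmin(axis=1)
                eta = self.eta0 / (1.0 + t_seen / tau)
                for k in np.unique(win):
                    sel = chunk[win == k]
                    code[k] += eta * (sel.mean(axis=0) - code[k])
                t_seen += len(chunk)
            if np.abs(code - prev).max() < self.tol:
                break

        # ascending intensity ordering of the codebook
        order = np.argsort(code.mean(axis=1), kind="stable")
        self.cluster_centers_ = code[order]
        self.model_ = VQModel(
            codebook=self.cluster_centers_,
            class_count=self.n_classes,
            learning_schedule=f"eta_t = {self.eta0}/(1 + t/{tau:.1f})",
            iteration_count=passes,
        )
        self.labels_ = self.predict(X)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "cluster_centers_")
        return cdist(np.asarray(X, float), self.cluster_centers_).argmin(axis=1)


def online_vq(features: FeatureVectorSet, class_count: int,
              seed: int = 0, **kwargs) -> tuple[VQModel, np.ndarray]:
    """Functional wrapper around :class:`OnlineVQ` on a feature set."""
    vq = OnlineVQ(n_classes=class_count, random_state=seed, **kwargs).fit(features.vectors)
    return vq.model_, vq.labels_
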