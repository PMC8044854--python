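"""Conventional baseline: flatten + zero-pad, PCA (>=95% variance), RBF-SVM.

Crops are flattened row-major per channel, concatenated across channels and
zero-padded to the largest training-set vector length. PCA is fitted on the
training portion only and retains the minimal prefix of components whose
cumulative explained variance reaches 95%; validation rows are transformed
with the same fit and never influence the projection. The SVM uses an RBF
kernel with C = 1, balanced class weights, and the kernel coefficient

    gamma = 1 / (n_dims * sample variance)

where the sample variance is taken over all entries of the projected training
feature matrix (the 'scale' convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from gadnet.dataset import CellImage, LABEL_TO_INDEX


def flatten_and_pad(
    images: list[CellImage], target_length: int | None = None
) -> tuple[np.ndarray, int]:
    """Flatten crops into rows of a feature matrix.

    Each crop is flattened row-major per channel and concatenated across
    channels. Without ``target_length`` rows are zero-padded to the longest
    crop in ``images`` (training behavior); with it, rows are padded — or, for
    oversize crops, truncated with a warning — to exactly that length
    (validation behavior). Returns (matrix, row length).
    """
    if not images:
        raise ValueError("cannot flatten an empty image list")
    flats = [img.values.reshape(-1) for img in images]
    length = target_length if target_length is not None else max(len(f) for f in flats)
    rows = np.zeros((len(flats), length), dtype=np.float64)
    for i, f in enumerate(flats):
        if len(f) > length:
            warnings.warn(
                f"crop {images[i].cell_id} exceeds the training feature length "
                f"({len(f)} > {length}); truncating",
                stacklevel=2,
            )
            f = f[:length]
        rows[i, : len(f)] = f
    return rows, length


def compute_gamma(n_dims: int, sample_variance: float) -> float:
    """gamma = 1 / (n_dims * sample_variance)."""
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    if sample_variance <= 0:
        raise ValueError("sample variance must be positive")
    return 1.0 / (n_dims * sample_variance)


@dataclass
class PcaProjection:
    """A PCA fit retaining the minimal >=95%-variance component prefix."""

    pca: PCA
    n_components: int
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform(X)


def fit_pca(X_train: np.ndarray, variance_target: float = 0.95) -> PcaProjection:
    """Fit PCA on the training matrix; keep the minimal prefix of components
    whose cumulative explained variance ratio reaches ``variance_target``."""
    if X_train.shape[0] < 2:
        raise ValueError("PCA requires at least two training rows")
    if not np.isfinite(X_train).all():
        raise ValueError("training matrix contains non-finite values")
    full = PCA(svd_solver="full")
    full.fit(X_train)
    ratios = full.explained_variance_ratio_
    cumulative = np.cumsum(ratios)
    if cumulative[-1] <= 0:
        raise ValueError("degenerate training matrix: zero total variance")
    n_keep = int(np.searchsorted(cumulative, variance_target) + 1)
    n_keep = min(n_keep, len(ratios))
    pca = PCA(n_components=n_keep, svd_solver="full")
    pca.fit(X_train)
    return PcaProjection(
        pca=pca, n_components=n_keep, explained_variance_ratio=pca.explained_variance_ratio_
    )


class PcaSvmModel:
    """flatten -> zero-pad -> PCA(>=95%) -> RBF-SVM(C=1, balanced weights).

    Fit on training crops only; the feature length, projection and gamma are
    all frozen at fit time so validation data cannot leak into them.
    """

    def __init__(self, C: float = 1.0, variance_target: float = 0.95):
        self.C = C
        self.variance_target = variance_target
        self.feature_length_: int | None = None
        self.projection_: PcaProjection | None = None
        self.gamma_: float | None = None
        self.svc_: SVC | None = None

    def fit(self, images: list[CellImage]) -> "PcaSvmModel":
        y = np.array([LABEL_TO_INDEX[img.label] for img in images])
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        X, self.feature_length_ = flatten_and_pad(images)
        self.projection_ = fit_pca(X, self.variance_target)
        Z = self.projection_.transform(X)
        self.gamma_ = compute_gamma(Z.shape[1], float(Z.var()))
        self.svc_ = SVC(
            kernel="rbf", C=self.C, gamma=self.gamma_, class_weight="balanced"
        )
        self.svc_.fit(Z, y)
        return self

    def _project(self, images: list[CellImage]) -> np.ndarray:
        if self.svc_ is None:
            raise RuntimeError("model is not fitted")
        X, _ = flatten_and_pad(images, target_length=self.feature_length_)
        return self.projection_.transform(X)

    def predict(self, images: list[CellImage]) -> np.ndarray:
        """Predicted class indices (0 = negative, 1 = positive)."""
        return self.svc_.predict(self._project(images))

    def manifest(self) -> dict:
        return {
            "model": "PCA-SVM",
            "C": self.C,
            "gamma": self.gamma_,
            "n_components": self.projection_.n_components if self.projection_ else None,
            "feature_length": self.feature_length_,
            "class_weight": "balanced",
            "variance_target": self.variance_target,
        }
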