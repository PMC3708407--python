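"""Two-dimensional PCA on image matrices, bilateral projection, and
projection-value statistics.

Classical PCA vectorizes each image before computing a covariance matrix;
2D-PCA instead works directly on the image matrices.  Given M training
images A_i with mean image A-bar, the image covariance (total-scatter)
matrix is

    S = (1/M) sum_i (A_i - A-bar)^T (A_i - A-bar),

an n x n symmetric PSD matrix for m x n images.  Its leading orthonormal
eigenvectors x_1..x_d are the optimal projection directions: y_k = A x_k
maximizes the projected scatter.  Projecting from both sides (column-side
directions from S, row-side directions from the covariance of the
transposed images) compresses an image to a small d x d feature matrix
B = X^T (A - A-bar) Y, flattened row-major to a 1 x d^2 feature vector.
With d = 7 this yields the 49-element descriptor used by the method-1
pipeline; the six summary statistics of those projection values (min, max,
mean, population std, variance, third central moment) form the method-2
descriptor.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

STAT_NAMES = ["stat_min", "stat_max", "stat_mean", "stat_std", "stat_var",
              "stat_moment3"]


def pca_feature_names(d: int) -> list[str]:
    width = max(2, len(str(d * d - 1)))
    return [f"pca_{i:0{width}d}" for i in range(d * d)]


@dataclasses.dataclass
class ImageCovariance:
    """Image covariance matrix S, the training mean image, and M."""

    matrix: np.ndarray
    mean_image: np.ndarray
    n_train: int

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance matrix not symmetric")


@dataclasses.dataclass
class ProjectionBasis:
    """Orthonormal eigenvectors (columns) with eigenvalues sorted descending."""

    column_vectors: np.ndarray
    eigenvalues: np.ndarray

    @property
    def variance_fractions(self) -> np.ndarray:
        ev = np.clip(self.eigenvalues, 0.0, None)
        total = ev.sum()
        if total <= 0:
            out = np.zeros_like(ev)
            out[0] = 1.0
            return out
        return ev / total


@dataclasses.dataclass
class FeatureMatrix:
    """d x d bilateral projection B of one image; .flat is its row-major flatten."""

    values: np.ndarray

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def flat(self) -> np.ndarray:
        return self.values.reshape(-1)


def image_covariance(train_images: Sequence[np.ndarray]) -> ImageCovariance:
    """Image covariance S = (1/M) sum (A_i - A-bar)^T (A_i - A-bar)."""
    if len(train_images) < 2:
        raise ValueError("need at least 2 training images")
    shape = train_images[0].shape
    for a in train_images:
        if a.shape != shape:
            raise ValueError(f"image shape mismatch: {a.shape} vs {shape}")
    stack = np.asarray(train_images, dtype=np.float64)
    mean = stack.mean(axis=0)
    centered = stack - mean
    # sum over images i and rows m: (C_i^T C_i)_{kl}
    s = np.einsum("imk,iml->kl", centered, centered) / len(train_images)
    s = (s + s.T) / 2
    return ImageCovariance(matrix=s, mean_image=mean, n_train=len(train_images))


def principal_directions(cov: ImageCovariance) -> ProjectionBasis:
    """Full eigendecomposition of S, eigenvalues descending.

    Sign convention: the largest-magnitude entry of each eigenvector is made
    positive, so feature tables are reproducible across platforms.
    """
    if not np.all(np.isfinite(cov.matrix)):
        raise ValueError("non-finite covariance entries")
    evals, evecs = np.linalg.eigh(cov.matrix)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    return ProjectionBasis(column_vectors=evecs, eigenvalues=evals)


def select_dimension(basis: ProjectionBasis, threshold: float = 0.99) -> int:
    """Smallest d whose cumulative variance fraction reaches ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    fractions = basis.variance_fractions
    cum = np.cumsum(fractions)
    if threshold == 1.0:
        nonzero = int(np.sum(np.clip(basis.eigenvalues, 0, None) > 0))
        return max(1, nonzero)
    d = int(np.searchsorted(cum, threshold - 1e-12)) + 1
    return min(max(d, 1), len(fractions))


def project_bilateral(
    image: np.ndarray,
    row_basis: ProjectionBasis,
    col_basis: ProjectionBasis,
    d: int,
    mean_image: np.ndarray | None = None,
) -> FeatureMatrix:
    """B = X^T (A - A-bar) Y with the top-d row- and column-side directions."""
    a = np.asarray(image, dtype=np.float64)
    if mean_image is not None:
        a = a - mean_image
    if d > row_basis.column_vectors.shape[1] or d > col_basis.column_vectors.shape[1]:
        raise ValueError(f"d={d} exceeds available eigenvectors")
    x = row_basis.column_vectors[:, :d]
    y = col_basis.column_vectors[:, :d]
    return FeatureMatrix(values=x.T @ a @ y)


def feature_distance(b_i: FeatureMatrix, b_j: FeatureMatrix) -> float:
    """Sum over columns k of the Euclidean distance between projected
    feature vectors y_k of the two matrices."""
    if b_i.values.shape != b_j.values.shape:
        raise ValueError("feature matrix shape mismatch")
    diff = b_i.values - b_j.values
    return float(np.sqrt((diff ** 2).sum(axis=0)).sum())


def nearest_neighbor_label(
    query: FeatureMatrix, references: Sequence[tuple[FeatureMatrix, str]]
) -> str:
    """Label of the reference minimizing ``feature_distance``; ties go to the
    lowest reference index."""
    if not references:
        raise ValueError("empty reference set")
    best_label, best_dist = references[0][1], feature_distance(query, references[0][0])
    for ref, label in references[1:]:
        dist = feature_distance(query, ref)
        if dist < best_dist:
            best_dist, best_label = dist, label
    return best_label


def summarize_projection(v: np.ndarray) -> np.ndarray:
    """Six statistics of a projection vector: min, max, mean, std, var,
    third central moment.  Std and var use the population convention
    (divide by n), so std**2 == var exactly."""
    v = np.asarray(v, dtype=np.float64).reshape(-1)
    if v.size < 2:
        raise ValueError("need at least 2 projection values")
    mean = v.mean()
    var = float(((v - mean) ** 2).mean())
    m3 = float(((v - mean) ** 3).mean())
    return np.array([v.min(), v.max(), mean, np.sqrt(var), var, m3])


class BilateralPCA:
    """Fitted bilateral 2D-PCA transform.

    ``fit`` computes the column-side covariance of the training images and
    the row-side covariance of their transposes, keeping both full
    eigenbases; ``transform`` projects a (mean-centered) image to its d x d
    feature matrix.
    """

    def __init__(self, d: int = 7) -> None:
        self.d = d
        self.mean_image: np.ndarray | None = None
        self.row_basis: ProjectionBasis | None = None
        self.col_basis: ProjectionBasis | None = None

    def fit(self, train_images: Sequence[np.ndarray]) -> "BilateralPCA":
        col_cov = image_covariance(train_images)
        row_cov = image_covariance([a.T for a in train_images])
        self.mean_image = col_cov.mean_image
        self.col_basis = principal_directions(col_cov)
        self.row_basis = principal_directions(row_cov)
        return self

    def transform(self, image: np.ndarray) -> FeatureMatrix:
        if self.mean_image is None:
            raise RuntimeError("BilateralPCA is not fitted")
        return project_bilateral(
            image, self.row_basis, self.col_basis, self.d, self.mean_image
        )

    def transform_flat(self, image: np.ndarray) -> np.ndarray:
        return self.transform(image).flat
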