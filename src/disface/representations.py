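"""Comparing latent spaces: canonical correlation analysis and PCA
reduction of external embeddings to a common dimensionality.

The CCA similarity between two stimulus-aligned embedding matrices is the
mean canonical correlation over min(dims) components (configurable to the
first component only).  Columns are standardized first and a small ridge is
added to the within-set covariances for numerical stability, so the measure
is invariant to invertible linear transforms of either space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.decomposition import PCA

__all__ = ["EmbeddingMatrix", "cca_similarity", "canonical_correlations", "pca_reduce"]

RIDGE = 1e-8


@dataclass
class EmbeddingMatrix:
    values: np.ndarray  # stimuli x features
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("embedding must be 2-D with at least 2 rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding entries must be finite")


def _as_values(E) -> np.ndarray:
    return E.values if isinstance(E, EmbeddingMatrix) else np.asarray(E, dtype=float)


def canonical_correlations(A, B, ridge: float = RIDGE) -> np.ndarray:
    """All canonical correlations between two row-aligned matrices.

    Classical CCA: standardize columns, whiten each set by its (ridge-
    regularized) covariance, then take the singular values of the
    cross-covariance of the whitened sets, clipped to [0, 1].
    """
    X = _as_values(A)
    Y = _as_values(B)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("matrices must have the same number of rows")
    n = X.shape[0]
    if n <= max(X.shape[1], Y.shape[1]):
        raise ValueError(
            f"need more rows ({n}) than columns "
            f"({X.shape[1]} and {Y.shape[1]}) for CCA"
        )

    def _standardize(M):
        M = M - M.mean(axis=0)
        sd = M.std(axis=0)
        if np.any(sd == 0):
            warnings.warn("constant column(s): left unscaled")
            sd = np.where(sd == 0, 1.0, sd)
        return M / sd

    X = _standardize(X)
    Y = _standardize(Y)
    Cxx = X.T @ X / n
    Cyy = Y.T @ Y / n
    Cxy = X.T @ Y / n
    for C, name in ((Cxx, "A"), (Cyy, "B")):
        if np.linalg.matrix_rank(C, tol=1e-10) < C.shape[0]:
            warnings.warn(f"matrix {name} is rank-deficient; ridge fallback in use")
    Cxx = Cxx + ridge * np.eye(X.shape[1])
    Cyy = Cyy + ridge * np.eye(Y.shape[1])
    Wx = linalg.inv(linalg.sqrtm(Cxx).real)
    Wy = linalg.inv(linalg.sqrtm(Cyy).real)
    s = linalg.svdvals(Wx @ Cxy @ Wy)
    return np.clip(s, 0.0, 1.0)


def cca_similarity(A, B, summary: str = "mean") -> float:
    """CCA similarity between two embedding spaces.

    ``summary='mean'`` (default): mean canonical correlation over the
    min(dims) components; ``'first'``: the first canonical correlation.
    """
    s = canonical_correlations(A, B)
    k = min(_as_values(A).shape[1], _as_values(B).shape[1])
    s = s[:k]
    if summary == "mean":
        return float(s.mean())
    if summary == "first":
        return float(s[0])
    raise ValueError(f"unknown summary {summary!r}")


def pca_reduce(E, k: int) -> tuple[np.ndarray, float]:
    """Column-centered PCA to ``k`` components.

    Returns the reduced (stimuli x k) matrix and the fraction of variance
    the top-k components capture.
    """
    X = _as_values(E)
    if k > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError(
            f"k={k} exceeds min(rows-1, features) = "
            f"{min(X.shape[0] - 1, X.shape[1])}"
        )
    pca = PCA(n_components=k, svd_solver="full")
    reduced = pca.fit_transform(X)
    return reduced, float(pca.explained_variance_ratio_.sum())
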