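"""PCA by singular value decomposition, and component-count selection.

PCA serves two roles here: exploratory score/loading trends of a single
preprocessed batch, and choosing the number of components F for the
curve-resolution step. Because the resolution is run on uncentered data,
the class supports both centered and uncentered decompositions; the
component count from uncentered data exceeds the centered count by one
whenever the data carry an offset-plus-low-rank (closure) structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCAModel", "RankSelection", "fit_pca", "select_rank"]


@dataclass
class PCAModel:
    """SVD-based principal component model.

    ``scores = (X - column_means) @ loadings`` when centered (the means are
    zero when not), and ``explained_variance_pct`` is each component's
    percentage of the total sum of squares of the (centered) matrix.
    """

    column_means: np.ndarray  # (N,); zeros when fitted uncentered
    loadings: np.ndarray  # (N, K), orthonormal columns
    scores: np.ndarray  # (M, K)
    explained_variance_pct: np.ndarray  # (K,)
    singular_values: np.ndarray  # all min(M, N) singular values
    centered: bool

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.column_means) @ self.loadings


def fit_pca(X: np.ndarray, K: int, center: bool = True) -> PCAModel:
    """Fit a K-component PCA by SVD.

    Sign convention: each loading vector is flipped so its
    largest-magnitude element is positive, making score plots reproducible
    across SVD implementations.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 rows")
    m, n = X.shape
    if not 1 <= K <= min(m, n):
        raise ValueError(f"K={K} must be in [1, {min(m, n)}]")
    if center:
        mu = X.mean(axis=0)
    else:
        mu = np.zeros(n)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt.T[:, :K].copy()
    # sign fix: largest-|.| element of each loading made positive
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(K)])
    flip[flip == 0] = 1.0
    V *= flip
    scores = Xc @ V
    total = float(np.sum(s**2))
    ev = 100.0 * s[:K] ** 2 / total if total > 0 else np.zeros(K)
    return PCAModel(
        column_means=mu,
        loadings=V,
        scores=scores,
        explained_variance_pct=ev,
        singular_values=s,
        centered=center,
    )


@dataclass
class RankSelection:
    """Component counts from uncentered and centered singular spectra."""

    F: int
    F_centered: int
    singular_values: np.ndarray
    singular_values_centered: np.ndarray
    threshold: float

    @property
    def offset_structure(self) -> bool:
        """True when centering removed exactly one component."""
        return self.F == self.F_centered + 1


def _count_above(s: np.ndarray, threshold: float) -> int:
    """Smallest F with every later singular value below threshold * s[0]."""
    if s.size == 0 or s[0] == 0:
        return 0
    below = s < threshold * s[0]
    # F = index of last value not below the cut, + 1
    keep = np.where(~below)[0]
    return int(keep[-1] + 1) if keep.size else 0


def select_rank(X: np.ndarray, threshold: float = 1e-3) -> RankSelection:
    """Choose the component count F from the singular-value spectrum.

    F is the smallest count such that singular values F+1 onward each fall
    below ``threshold`` times the first. The centered matrix is analyzed
    the same way; when the data carry a closure (offset) relation, the
    centered count is one lower.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    s = np.linalg.svd(X, compute_uv=False)
    sc = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    return RankSelection(
        F=_count_above(s, threshold),
        F_centered=_count_above(sc, threshold),
        singular_values=s,
        singular_values_centered=sc,
        threshold=threshold,
    )
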