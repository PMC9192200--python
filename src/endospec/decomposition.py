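"""Principal component analysis by singular value decomposition.

The bilinear model X = T P^T + E on column-centred data: T (scores, n x k)
describes relations among samples, P (loadings, m x k) the dependencies
between variables, and E the rank-k residual, which is minimal in the
Frobenius norm among all rank-k approximations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray          # P, m x k, orthonormal columns
    scores: np.ndarray            # T, n x k, mutually orthogonal columns
    explained_variance_ratio: np.ndarray
    k: int
    _Xc: np.ndarray = field(repr=False, default=None)

    def residual(self) -> np.ndarray:
        """E = Xc - T P^T for the training data."""
        return self._Xc - self.scores @ self.loadings.T


def pca_fit(X: np.ndarray, k: int) -> PCAModel:
    """Centre columns and decompose via SVD.

    Sign convention: each loading column is flipped so its largest-magnitude
    entry is positive, removing the SVD sign ambiguity deterministically.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if not 1 <= k <= min(n - 1, m):
        raise ValueError(f"k must be in [1, {min(n - 1, m)}], got {k}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic signs
    P = Vt[:k].T
    flip = np.sign(P[np.argmax(np.abs(P), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    P = P * flip
    T = (U[:, :k] * s[:k]) * flip
    total = float(np.sum(s**2))
    ratio = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCAModel(mean=mean, loadings=P, scores=T,
                    explained_variance_ratio=ratio, k=k, _Xc=Xc)


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project new rows onto the fitted components."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return (X - model.mean) @ model.loadings
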