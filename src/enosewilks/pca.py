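"""Covariance-based principal component analysis.

PCA is performed on the *unstandardized* feature matrix: the sample covariance
matrix (divisor ``n - 1``) of the mean-centered D_ave features is
eigendecomposed, eigenvalues sorted descending, and each eigenvector's sign
fixed so its largest-magnitude entry is positive (ties broken by lowest
index).  No correlation scaling is applied — the eigenvalue magnitudes of raw
D_ave features (1e-5 .. 1e-11 for typical metal-oxide arrays) are meaningful
and carried through to every report.

The model is fitted on all samples (train and test together); the PNN split
happens downstream.  This mirrors the standard e-nose workflow in which PCA is
an unsupervised visualisation step preceding classification; the information
leakage it implies for accuracy estimates is documented, not silently changed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .exceptions import InsufficientDataError, ShapeError
from .features import FeatureMatrix

__all__ = ["PCAModel", "ScoreMatrix", "fit_pca", "transform", "explained_variance_pct"]

_EIG_CLIP = -1e-12


@dataclass
class PCAModel:
    """Fitted PCA: per-sensor means, orthonormal loadings, eigenvalues.

    ``loadings`` columns are eigenvectors in descending-eigenvalue order;
    ``eigenvalues`` are non-negative (tiny negative round-off clipped to 0).
    """

    mean_vector: np.ndarray  # (p,)
    loadings: np.ndarray  # (p, p)
    eigenvalues: np.ndarray  # (p,), descending

    @property
    def n_features(self) -> int:
        return self.mean_vector.size


@dataclass
class ScoreMatrix:
    """Samples x PCs projection with labels; component_ids are 1-based."""

    scores: np.ndarray  # (n_samples, n_components)
    labels: list[str]
    sample_ids: list[str]
    component_ids: list[int]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ShapeError("scores must be 2-D")
        if self.scores.shape[1] != len(self.component_ids):
            raise ShapeError("component_ids length must match score columns")

    @property
    def classes(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def select(self, component_ids: Iterable[int]) -> "ScoreMatrix":
        """Restrict to the given 1-based PC indices (order preserved)."""
        ids = list(component_ids)
        try:
            cols = [self.component_ids.index(i) for i in ids]
        except ValueError as e:
            raise ShapeError(f"component id not present: {e}") from e
        return ScoreMatrix(self.scores[:, cols], self.labels, self.sample_ids, ids)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|.| entry is positive (lowest index on ties)."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        idx = int(np.argmax(np.abs(col)))  # argmax returns the first maximal index
        if col[idx] < 0:
            out[:, j] = -col
    return out


def fit_pca(fm: FeatureMatrix | np.ndarray) -> PCAModel:
    """Eigendecompose the sample covariance (divisor n-1) of centered features."""
    X = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)
    n, p = X.shape
    if n < 2:
        raise InsufficientDataError(f"PCA needs >= 2 samples, got {n}")
    mean = X.mean(axis=0)
    C = np.cov(X - mean, rowvar=False, ddof=1).reshape(p, p)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if np.any(evals < _EIG_CLIP * max(1.0, float(np.abs(evals).max()))):
        # eigh of a PSD matrix: anything more negative than round-off is a bug
        raise ValueError("covariance eigendecomposition produced a negative eigenvalue")
    evals = np.clip(evals, 0.0, None)
    return PCAModel(mean, _fix_signs(evecs), evals)


def transform(model: PCAModel, fm: FeatureMatrix | np.ndarray) -> ScoreMatrix:
    """Project features onto all principal components: (X - mean) @ loadings."""
    if isinstance(fm, FeatureMatrix):
        X, labels, ids = fm.values, fm.labels, fm.sample_ids
    else:
        X = np.asarray(fm, dtype=float)
        labels = [""] * X.shape[0]
        ids = [str(i) for i in range(X.shape[0])]
    if X.shape[1] != model.n_features:
        raise ShapeError(
            f"feature dimension {X.shape[1]} != model dimension {model.n_features}"
        )
    scores = (X - model.mean_vector) @ model.loadings
    return ScoreMatrix(scores, list(labels), list(ids), list(range(1, X.shape[1] + 1)))


def explained_variance_pct(eigenvalues, components: Iterable[int]) -> float:
    """Percentage of total variance captured by the given 1-based components.

    Returns full precision; round to 2 decimals for display.
    """
    lam = np.asarray(list(eigenvalues), dtype=float)
    comp = sorted(set(int(c) for c in components))
    if not comp:
        raise ValueError("component set must be non-empty")
    if comp[0] < 1 or comp[-1] > lam.size:
        raise ValueError(f"component indices out of range 1..{lam.size}: {comp}")
    total = lam.sum()
    if total <= 0:
        raise ValueError("total variance must be positive")
    return float(100.0 * lam[[c - 1 for c in comp]].sum() / total)
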