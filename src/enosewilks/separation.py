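"""Class centroids and pairwise Mahalanobis distances in a 2-PC subspace.

Each class's centroid is the arithmetic mean of its score rows,
(x_ave, y_ave).  Distances between centroids are Mahalanobis distances

    MD(g, h) = sqrt((c_g - c_h)^T  S_w^{-1}  (c_g - c_h))

whitened by the *pooled within-class covariance* S_w (divisor N - c), the
standard choice in discriminant analysis.  Pooling makes the distance scale
invariant across PC pairs, so separation tables computed for different pairs
are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError, SingularityError
from .pca import ScoreMatrix

__all__ = ["CentroidSet", "centroids", "pairwise_md"]


@dataclass
class CentroidSet:
    """Per-class 2-D centroids with the pooled within-class covariance."""

    centroids: np.ndarray  # (c, 2)
    pooled_cov: np.ndarray  # (2, 2)
    classes: list[str]
    component_ids: tuple[int, ...]


def centroids(scores, labels=None) -> CentroidSet:
    """Class means and pooled within-class covariance of 2-D scores."""
    if isinstance(scores, ScoreMatrix):
        X = scores.scores
        comp_ids = tuple(scores.component_ids)
        if labels is None:
            labels = scores.labels
    else:
        X = np.asarray(scores, dtype=float)
        comp_ids = tuple(range(1, X.shape[1] + 1))
        if labels is None:
            raise ValueError("labels are required when scores is a plain array")
    labels = list(labels)
    if X.shape[1] != 2:
        raise ValueError(f"centroid analysis is defined on 2 components, got {X.shape[1]}")
    classes: list[str] = []
    for lab in labels:
        if lab not in classes:
            classes.append(lab)
    lab_arr = np.asarray(labels)
    cents = np.empty((len(classes), 2))
    pooled = np.zeros((2, 2))
    n_total = 0
    for g, cls in enumerate(classes):
        Xg = X[lab_arr == cls]
        if Xg.shape[0] < 2:
            raise InsufficientDataError(
                f"class {cls!r} has {Xg.shape[0]} sample(s); pooled covariance needs >= 2"
            )
        cents[g] = Xg.mean(axis=0)
        dev = Xg - cents[g]
        pooled += dev.T @ dev
        n_total += Xg.shape[0]
    pooled /= n_total - len(classes)
    return CentroidSet(cents, pooled, classes, comp_ids)


def pairwise_md(cs: CentroidSet) -> dict[tuple[str, str], float]:
    """Mahalanobis distance for every unordered class pair.

    Returns a dict keyed by (class_g, class_h) in class order, g < h.  A
    singular pooled covariance raises with a regularisation hint
    (eps = 1e-12 * trace added to the diagonal restores invertibility).
    """
    S = cs.pooled_cov
    try:
        S_inv = np.linalg.inv(S)
    except np.linalg.LinAlgError as e:
        raise SingularityError(
            "pooled within-class covariance is singular; consider regularising "
            f"with eps*I, eps = 1e-12*trace = {1e-12 * np.trace(S):.3e}"
        ) from e
    out: dict[tuple[str, str], float] = {}
    for g in range(len(cs.classes)):
        for h in range(g + 1, len(cs.classes)):
            d = cs.centroids[g] - cs.centroids[h]
            md2 = float(d @ S_inv @ d)
            out[(cs.classes[g], cs.classes[h])] = float(np.sqrt(max(md2, 0.0)))
    return out
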