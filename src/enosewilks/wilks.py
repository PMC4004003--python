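"""Wilks lambda dispersion ratios for principal-component subset selection.

For a chosen set of ``m`` principal components, two ``m x m`` scatter matrices
are accumulated over classes ``g`` and samples ``k``:

* within-class scatter ``D``:  d_ij = sum_g sum_k (X_igk - u_ig)(X_jgk - u_jg)
* total scatter ``A``:         a_ij = sum_g sum_k (X_igk - u_i )(X_jgk - u_j )

with per-class means ``u_ig`` and grand means ``u_i``.  The dispersion ratio
is the Wilks lambda statistic  Λ = det(D)/det(A); small Λ means the classes
are well separated relative to the total spread.

The *improved* variant replaces each cross-product term by its absolute value
before summation, preventing sign cancellation in the off-diagonal entries
when deviations along two components disagree in sign.  Diagonal entries
(squares) are unchanged.  The improved Λ is not guaranteed to lie in [0, 1]
and is flagged in the report if it exceeds 1; the regular Λ always lies in
[0, 1] since A = D + between-class scatter with both terms PSD.

``pair_search`` evaluates Λ for every unordered component pair and selects
the minimiser (lexicographic tie-break), optionally over all k-subsets for
m <= 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .exceptions import InsufficientDataError, SingularityError
from .pca import ScoreMatrix

__all__ = [
    "ScatterPair",
    "WilksReport",
    "scatter_matrices",
    "wilks_lambda",
    "pair_search",
    "select_best_pair",
]

VARIANTS = ("regular", "improved")

_DET_FLOOR = 1e-300


@dataclass
class ScatterPair:
    """Within-class (D) and total (A) scatter matrices for one component set."""

    D: np.ndarray
    A: np.ndarray
    variant: str
    component_ids: tuple[int, ...]


@dataclass
class WilksReport:
    """Λ over all component subsets plus the selected minimiser.

    ``ratios`` maps the (1-based, sorted) component tuple to its Λ value at
    full precision; display rounding to 4 decimals is left to the caller.
    ``flagged`` lists subsets whose Λ exceeds 1 (possible only for the
    improved variant).
    """

    ratios: dict[tuple[int, ...], float]
    variant: str
    best_pair: tuple[int, ...]
    best_value: float
    flagged: list[tuple[int, ...]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "ratios": [[*pair, val] for pair, val in sorted(self.ratios.items())],
            "best_pair": list(self.best_pair),
            "best_value": self.best_value,
            "flagged": [list(p) for p in self.flagged],
        }


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")


def scatter_matrices(
    scores, labels: Sequence[str] | None = None, variant: str = "regular"
) -> ScatterPair:
    """Accumulate D and A over the given scores (n_samples x m).

    ``scores`` may be a :class:`~enosewilks.pca.ScoreMatrix` (its labels are
    used unless ``labels`` is given) or a plain array.
    """
    _check_variant(variant)
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
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("scores must be n_samples x m with m >= 1")
    if len(labels) != X.shape[0]:
        raise ValueError("labels length must match sample count")
    classes: list[str] = []
    for lab in labels:
        if lab not in classes:
            classes.append(lab)
    if len(classes) < 2:
        raise InsufficientDataError("scatter matrices need >= 2 classes")
    lab_arr = np.asarray(labels)
    grand = X.mean(axis=0)
    m = X.shape[1]
    D = np.zeros((m, m))
    A = np.zeros((m, m))
    for g in classes:
        Xg = X[lab_arr == g]
        if Xg.shape[0] == 0:
            raise ValueError(f"class {g!r} has no samples")
        dev_w = Xg - Xg.mean(axis=0)
        dev_t = Xg - grand
        if variant == "regular":
            D += dev_w.T @ dev_w
            A += dev_t.T @ dev_t
        else:
            # absolute value of each cross-product term before summation
            D += np.einsum("ki,kj->ij", np.abs(dev_w), np.abs(dev_w))
            A += np.einsum("ki,kj->ij", np.abs(dev_t), np.abs(dev_t))
    return ScatterPair(D, A, variant, comp_ids)


def _det2_compensated(M: np.ndarray) -> float:
    """2x2 determinant ad - bc accumulated in extended precision."""
    a, b = np.longdouble(M[0, 0]), np.longdouble(M[0, 1])
    c, d = np.longdouble(M[1, 0]), np.longdouble(M[1, 1])
    return float(a * d - b * c)


def _det(M: np.ndarray) -> float:
    if M.shape == (1, 1):
        return float(M[0, 0])
    if M.shape == (2, 2):
        return _det2_compensated(M)
    return float(np.linalg.det(M))


def wilks_lambda(sp: ScatterPair) -> float:
    """Λ = det(D)/det(A) for one scatter pair."""
    det_A = _det(sp.A)
    if abs(det_A) < _DET_FLOOR:
        raise SingularityError(
            f"det(A) ~ 0 for components {sp.component_ids}; "
            "use fewer components or more samples"
        )
    return _det(sp.D) / det_A


def select_best_pair(
    ratios: Mapping[tuple[int, ...], float]
) -> tuple[tuple[int, ...], float]:
    """Arg-min of a Λ table; ties resolved to the lexicographically lowest subset."""
    if not ratios:
        raise ValueError("empty ratio table")
    best_pair = min(sorted(ratios), key=lambda p: ratios[p])
    return tuple(best_pair), float(ratios[best_pair])


def pair_search(
    scores,
    labels: Sequence[str] | None = None,
    variant: str = "improved",
    components: Sequence[int] | None = None,
    subset_size: int = 2,
) -> WilksReport:
    """Λ for every ``subset_size``-subset of components; returns the minimiser.

    ``subset_size`` may be 2 (the standard pair search) or 3 (exhaustive
    triple search).  Singularity errors are re-raised annotated with the
    offending subset.
    """
    _check_variant(variant)
    if subset_size not in (2, 3):
        raise ValueError("subset_size must be 2 or 3")
    if isinstance(scores, ScoreMatrix):
        sm = scores
        if labels is None:
            labels = sm.labels
    else:
        X = np.asarray(scores, dtype=float)
        sm = ScoreMatrix(
            X, list(labels), [str(i) for i in range(X.shape[0])],
            list(range(1, X.shape[1] + 1)),
        )
    avail = list(sm.component_ids) if components is None else [int(c) for c in components]
    if len(avail) < subset_size:
        raise InsufficientDataError(
            f"need >= {subset_size} components, have {len(avail)}"
        )
    ratios: dict[tuple[int, ...], float] = {}
    flagged: list[tuple[int, ...]] = []
    for subset in combinations(sorted(avail), subset_size):
        sub = sm.select(subset)
        sp = scatter_matrices(sub, list(labels), variant)
        try:
            lam = wilks_lambda(sp)
        except SingularityError as e:
            raise SingularityError(f"components {subset}: {e}") from e
        ratios[subset] = lam
        if lam > 1.0 + 1e-12:
            flagged.append(subset)
    best_pair, best_value = select_best_pair(ratios)
    return WilksReport(ratios, variant, best_pair, best_value, flagged)
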