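"""Probabilistic neural network (Parzen-kernel) classification.

A PNN stores one pattern neuron per training sample.  For a query vector the
pattern layer computes a kernel activation against every stored pattern, the
summation layer adds activations per class, and the output layer returns the
arg-max class.  Two kernels are provided:

* ``dot_product`` (default) — patterns and queries are unit-normalized and the
  activation is  g(z) = exp((z - 1) / sigma^2)  with  z = <query, pattern>.
  On unit vectors this equals exp(-||x - w||^2 / (2 sigma^2)), the Gaussian
  Parzen kernel, since ||x - w||^2 = 2(1 - z).
* ``euclidean`` — g = exp(-||x - w||^2 / (2 sigma^2)) on the raw vectors,
  matching MATLAB's ``newpnn`` radial-basis behaviour.  The two kernels differ
  on un-normalized data.

The spread sigma is the kernel bandwidth: as sigma -> 0 the PNN reduces to a
1-nearest-neighbour classifier (in the kernel's own metric); as sigma -> inf
every class score converges to that class's pattern count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .exceptions import InsufficientDataError

__all__ = [
    "PNNModel",
    "ConfusionMatrix",
    "Prediction",
    "train_pnn",
    "predict",
    "predict_batch",
    "evaluate",
    "spread_grid_search",
    "DEFAULT_SPREAD_GRID",
    "split_first_k",
]

KERNELS = ("dot_product", "euclidean")

#: ten-point spread grid from 1e-5 to 1e-4 used for model selection
DEFAULT_SPREAD_GRID = tuple(k * 1e-5 for k in range(1, 11))

_TIE_REL = 1e-12


@dataclass
class PNNModel:
    patterns: np.ndarray  # (n_train, d); unit rows for dot_product
    pattern_class: np.ndarray  # (n_train,) class indices
    classes: list[str]
    spread: float
    kernel: str = "dot_product"
    normalize: bool = True

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]


class Prediction(NamedTuple):
    class_index: int
    class_label: str
    class_scores: np.ndarray  # summed activations per class
    tie: bool


@dataclass
class ConfusionMatrix:
    """c x c counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError(f"counts must be {c}x{c}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy_pct(self) -> float:
        """trace/total as a percentage (full precision; round to 2 dp to display)."""
        if self.total == 0:
            raise InsufficientDataError("empty confusion matrix has no accuracy")
        return float(100.0 * np.trace(self.counts) / self.total)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.counts, index=self.classes, columns=self.classes)
        df.loc["SUM"] = df.sum(axis=0)
        df["SUM"] = df.sum(axis=1)
        return df


def _normalize_rows(X: np.ndarray, what: str) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"zero-norm {what} vector under dot_product kernel")
    return X / norms[:, None]


def train_pnn(
    train_scores,
    labels: Sequence[str] | None = None,
    spread: float = 1e-4,
    kernel: str = "dot_product",
    normalize: bool = True,
) -> PNNModel:
    """Store the training patterns; a PNN has no iterative fitting step."""
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {KERNELS}, got {kernel!r}")
    if spread <= 0:
        raise ValueError(f"spread must be positive, got {spread}")
    from .pca import ScoreMatrix

    if isinstance(train_scores, ScoreMatrix):
        X = train_scores.scores
        if labels is None:
            labels = train_scores.labels
    else:
        X = np.asarray(train_scores, dtype=float)
        if labels is None:
            raise ValueError("labels are required when train_scores is a plain array")
    labels = list(labels)
    if X.shape[0] == 0:
        raise InsufficientDataError("cannot train a PNN without samples")
    classes: list[str] = []
    for lab in labels:
        if lab not in classes:
            classes.append(lab)
    idx = np.array([classes.index(lab) for lab in labels])
    patterns = X.astype(float, copy=True)
    if kernel == "dot_product" and normalize:
        patterns = _normalize_rows(patterns, "training")
    return PNNModel(patterns, idx, classes, float(spread), kernel, normalize)


def _exponents(model: PNNModel, Q: np.ndarray) -> np.ndarray:
    """Log pattern-layer activations for query rows Q; shape (n_query, n_patterns)."""
    s2 = model.spread**2
    if model.kernel == "dot_product":
        if model.normalize:
            Q = _normalize_rows(Q, "query")
        z = Q @ model.patterns.T
        return (z - 1.0) / s2
    d2 = ((Q[:, None, :] - model.patterns[None, :, :]) ** 2).sum(axis=2)
    return -d2 / (2.0 * s2)


def _activations(model: PNNModel, Q: np.ndarray) -> np.ndarray:
    """Pattern activations exp(exponent), rescued from underflow when needed.

    At very small spreads every raw activation can underflow to 0; for those
    queries the exponents are shifted by their maximum before exponentiating.
    The shift rescales all of a query's activations by a common positive
    factor, so class-score ratios and the arg-max are unaffected, and the
    small-spread nearest-neighbour limit holds numerically.
    """
    E = _exponents(model, Q)
    with np.errstate(under="ignore"):
        act = np.exp(E)
    dead = act.max(axis=1) == 0.0
    if np.any(dead):
        shifted = E[dead] - E[dead].max(axis=1, keepdims=True)
        act[dead] = np.exp(shifted)
    return act


def _class_scores(model: PNNModel, act: np.ndarray) -> np.ndarray:
    c = len(model.classes)
    scores = np.zeros((act.shape[0], c))
    for g in range(c):
        scores[:, g] = act[:, model.pattern_class == g].sum(axis=1)
    return scores


def predict(model: PNNModel, query) -> Prediction:
    """Classify one query vector; ties resolve to the lowest class index."""
    q = np.asarray(query, dtype=float).reshape(1, -1)
    if q.shape[1] != model.patterns.shape[1]:
        raise ValueError(
            f"query dimension {q.shape[1]} != pattern dimension {model.patterns.shape[1]}"
        )
    scores = _class_scores(model, _activations(model, q))[0]
    best = int(np.argmax(scores))  # argmax returns the first (lowest) maximal index
    top = scores[best]
    tie = bool(np.sum(scores >= top - _TIE_REL * max(abs(top), 1e-300)) > 1)
    return Prediction(best, model.classes[best], scores, tie)


def predict_batch(model: PNNModel, queries) -> list[Prediction]:
    Q = np.asarray(queries, dtype=float)
    scores = _class_scores(model, _activations(model, Q))
    out = []
    for row in scores:
        best = int(np.argmax(row))
        top = row[best]
        tie = bool(np.sum(row >= top - _TIE_REL * max(abs(top), 1e-300)) > 1)
        out.append(Prediction(best, model.classes[best], row, tie))
    return out


def evaluate(model: PNNModel, test_scores, test_labels=None) -> tuple[ConfusionMatrix, float]:
    """Confusion matrix and accuracy (%) of the model on a labelled test set."""
    from .pca import ScoreMatrix

    if isinstance(test_scores, ScoreMatrix):
        X = test_scores.scores
        if test_labels is None:
            test_labels = test_scores.labels
    else:
        X = np.asarray(test_scores, dtype=float)
        if test_labels is None:
            raise ValueError("test labels are required")
    test_labels = list(test_labels)
    if X.shape[0] == 0:
        raise InsufficientDataError("empty test set")
    unseen = set(test_labels) - set(model.classes)
    if unseen:
        raise ValueError(f"test labels unseen in training: {sorted(unseen)}")
    c = len(model.classes)
    counts = np.zeros((c, c), dtype=int)
    for pred, lab in zip(predict_batch(model, X), test_labels):
        counts[model.classes.index(lab), pred.class_index] += 1
    cm = ConfusionMatrix(counts, list(model.classes))
    return cm, cm.accuracy_pct


def split_first_k(scores, labels=None, n_train_per_class: int = 15):
    """Per-class head/tail split: first k samples of each class train, rest test.

    The split follows stored sample order (no shuffling), the convention for
    sequentially acquired e-nose measurements.  Returns
    (X_train, y_train, X_test, y_test).
    """
    from .pca import ScoreMatrix

    if isinstance(scores, ScoreMatrix):
        X = scores.scores
        if labels is None:
            labels = scores.labels
    else:
        X = np.asarray(scores, dtype=float)
        if labels is None:
            raise ValueError("labels are required")
    labels = list(labels)
    counts: dict[str, int] = {}
    tr_idx, te_idx = [], []
    for i, lab in enumerate(labels):
        counts[lab] = counts.get(lab, 0) + 1
        (tr_idx if counts[lab] <= n_train_per_class else te_idx).append(i)
    if not te_idx:
        raise InsufficientDataError(
            f"no class has more than {n_train_per_class} samples; empty test set"
        )
    y = np.asarray(labels)
    return X[tr_idx], list(y[tr_idx]), X[te_idx], list(y[te_idx])


def spread_grid_search(
    X_train,
    y_train,
    X_test,
    y_test,
    grid: Sequence[float] = DEFAULT_SPREAD_GRID,
    kernel: str = "dot_product",
    normalize: bool = True,
) -> dict:
    """Evaluate every spread on the grid; select by the joint-accuracy rule.

    The selected spread is the smallest among those maximizing
    (train accuracy, test accuracy) lexicographically — i.e. the best model is
    the one where both accuracies are highest at the same time, preferring the
    tighter kernel on ties.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("spread grid must be non-empty")
    results = []
    for s in grid:
        model = train_pnn(X_train, y_train, spread=s, kernel=kernel, normalize=normalize)
        _, train_acc = evaluate(model, X_train, y_train)
        _, test_acc = evaluate(model, X_test, y_test)
        results.append({"spread": float(s), "train_acc": train_acc, "test_acc": test_acc})
    best_key = max((r["train_acc"], r["test_acc"]) for r in results)
    selected = min(
        r["spread"] for r in results if (r["train_acc"], r["test_acc"]) == best_key
    )
    return {"grid": results, "selected_spread": selected, "kernel": kernel}
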