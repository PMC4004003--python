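import numpy as np
import pytest

from enosewilks.data import Dataset, ResponseCurve


def make_random_dataset(
    rng: np.random.Generator,
    n_classes: int = 3,
    n_per_class: int = 4,
    n_sensors: int = 4,
    n_time: int = 10,
    dt: float = 1.0,
) -> Dataset:
    """Small valid dataset with positive ratios for structural tests."""
    curves = []
    for g in range(n_classes):
        for k in range(n_per_class):
            vals = rng.uniform(0.5, 3.0, size=(n_sensors, n_time))
            curves.append(
                ResponseCurve(f"c{g}-{k}", f"class{g}", vals, dt=dt)
            )
    return Dataset(curves)


def scatter_oracle(X, labels, variant):
    """Explicit double-loop accumulation of the within (D) and total (A)
    scatter matrices, term by term; independent of the vectorised path."""
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    classes = []
    for lab in labels:
        if lab not in classes:
            classes.append(lab)
    n, m = X.shape
    grand = [np.mean([X[k, i] for k in range(n)]) for i in range(m)]
    class_mean = {
        c: [
            np.mean([X[k, i] for k in range(n) if labels[k] == c])
            for i in range(m)
        ]
        for c in classes
    }
    D = np.zeros((m, m))
    A = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            for c in classes:
                for k in range(n):
                    if labels[k] != c:
                        continue
                    dterm = (X[k, i] - class_mean[c][i]) * (X[k, j] - class_mean[c][j])
                    aterm = (X[k, i] - grand[i]) * (X[k, j] - grand[j])
                    if variant == "improved":
                        dterm, aterm = abs(dterm), abs(aterm)
                    D[i, j] += dterm
                    A[i, j] += aterm
    return D, A


def det_oracle(M):
    """Determinant for 1x1/2x2 matrices by the textbook formula."""
    M = np.asarray(M, dtype=float)
    if M.shape == (1, 1):
        return M[0, 0]
    return M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
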