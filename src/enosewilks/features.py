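"""Mean-differential-coefficient feature extraction.

Each sensor's response curve is summarised by a single scalar, the mean
differential coefficient

    D_ave = (1/(n-1)) * sum_{z=1}^{n-1} (x_{z+1} - x_z) / dt,

the average first difference of the curve — i.e. its average response
velocity.  The sum telescopes to the closed form

    D_ave = (x_n - x_1) / ((n - 1) * dt),

which is the production path (O(1), numerically identical); the literal
summation form is retained as an independent oracle for testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd

from .data import Dataset
from .exceptions import InsufficientDataError, ShapeError

__all__ = ["FeatureMatrix", "dave", "dave_summation", "extract_features"]


@dataclass
class FeatureMatrix:
    """Samples x sensors matrix of D_ave values with per-row labels."""

    values: np.ndarray  # (n_samples, n_sensors), ratio units per second
    labels: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("feature matrix must be 2-D (samples x sensors)")
        if len(self.labels) != self.values.shape[0] or len(self.sample_ids) != self.values.shape[0]:
            raise ShapeError("labels/sample_ids length must match row count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def to_frame(self) -> pd.DataFrame:
        cols = [f"s{i+1}" for i in range(self.n_sensors)]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "class_label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        return path

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(
            path,
            dtype={"sample_id": str, "class_label": str},
            float_precision="round_trip",
        )
        cols = sorted(
            (c for c in df.columns if c.startswith("s") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        return cls(df[cols].to_numpy(float), list(df["class_label"]), list(df["sample_id"]))


def dave(series, dt: float = 1.0) -> float:
    """Mean differential coefficient of one time series (closed form)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ShapeError("dave expects a 1-D series")
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"dave needs >= 2 points, got {n}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return float((x[-1] - x[0]) / ((n - 1) * dt))


def dave_summation(series, dt: float = 1.0) -> float:
    """Literal summation form of D_ave; test oracle for :func:`dave`."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"dave needs >= 2 points, got {n}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return math.fsum((x[z + 1] - x[z]) / dt for z in range(n - 1)) / (n - 1)


def extract_features(ds: Dataset) -> FeatureMatrix:
    """D_ave per sensor per sample; rows follow dataset order."""
    if not ds.curves:
        raise InsufficientDataError("cannot extract features from an empty dataset")
    n_sensors = ds.n_sensors
    if len({c.n_sensors for c in ds.curves}) > 1:
        raise ShapeError("heterogeneous sensor counts")
    vals = np.empty((len(ds.curves), n_sensors))
    for k, c in enumerate(ds.curves):
        # closed form, vectorised over sensors
        vals[k] = (c.values[:, -1] - c.values[:, 0]) / ((c.n_time - 1) * c.dt)
    return FeatureMatrix(vals, ds.labels, ds.sample_ids)
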