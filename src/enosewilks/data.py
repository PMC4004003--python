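"""Data model and CSV IO for electronic-nose response records.

A *response curve* is one sample's sensor-array recording: for each of
``n_sensors`` metal-oxide sensors, the conductance ratio ``G/G0`` sampled at a
fixed interval ``dt`` over ``n_time`` points.  Ratios are dimensionless and
strictly positive.  A :class:`Dataset` is an ordered collection of such curves
with a stable class ordering (first appearance), which fixes the 0-based class
index used by every downstream stage.

Two CSV dialects are supported:

* ``long`` — columns ``sample_id, class_label, sensor, t, value``; one row per
  (sensor, time point).  Time is explicit, so any constant ``dt`` round-trips.
* ``wide`` — columns ``sample_id, class_label, sensor, v1..v{n_time}``; one row
  per sensor.  Time is implicit with ``dt = 1 s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DialectError, FormatError, InsufficientDataError, ShapeError

__all__ = ["ResponseCurve", "Dataset", "read_response_csv", "write_response_csv"]

_DT_TOL = 1e-9

_LONG_COLUMNS = ["sample_id", "class_label", "sensor", "t", "value"]


@dataclass
class ResponseCurve:
    """One sample's sensors x time matrix of G/G0 ratios.

    Parameters
    ----------
    sample_id : str
        Unique identifier of the physical sample.
    class_label : str
        Free-form class name (e.g. a grain variety).
    values : ndarray, shape (n_sensors, n_time)
        Strictly positive conductance ratios.
    dt : float
        Seconds between consecutive readings (default 1.0).
    """

    sample_id: str
    class_label: str
    values: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError(
                f"curve values must be 2-D (sensors x time), got ndim={self.values.ndim}"
            )
        if self.values.shape[1] < 2:
            raise InsufficientDataError(
                f"curve {self.sample_id!r} needs >= 2 time points, got {self.values.shape[1]}"
            )
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"curve {self.sample_id!r} contains non-finite ratios")
        if np.any(self.values <= 0):
            raise ValueError(
                f"curve {self.sample_id!r} contains non-positive ratios; "
                "G/G0 is strictly positive"
            )

    @property
    def n_sensors(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sampling times in seconds, starting at dt."""
        return self.dt * np.arange(1, self.n_time + 1)


@dataclass
class Dataset:
    """Ordered collection of response curves with a stable class ordering.

    ``classes`` is the list of distinct labels in first-appearance order; its
    positions define the 0-based class index ``g`` used internally (1-based in
    user-facing reports).
    """

    curves: list[ResponseCurve]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.classes:
            seen: list[str] = []
            for c in self.curves:
                if c.class_label not in seen:
                    seen.append(c.class_label)
            self.classes = seen
        missing = {c.class_label for c in self.curves} - set(self.classes)
        if missing:
            raise ValueError(f"curves carry labels not in classes: {sorted(missing)}")
        if self.curves:
            ns = {c.n_sensors for c in self.curves}
            if len(ns) > 1:
                raise ShapeError(f"heterogeneous sensor counts in dataset: {sorted(ns)}")

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves)

    @property
    def n_sensors(self) -> int:
        if not self.curves:
            raise InsufficientDataError("empty dataset has no sensor count")
        return self.curves[0].n_sensors

    @property
    def labels(self) -> list[str]:
        return [c.class_label for c in self.curves]

    @property
    def sample_ids(self) -> list[str]:
        return [c.sample_id for c in self.curves]

    def class_index(self, label: str) -> int:
        return self.classes.index(label)


def _infer_dt(times: np.ndarray, sample_id: str) -> float:
    steps = np.diff(np.sort(times))
    if steps.size == 0:
        raise InsufficientDataError(f"sample {sample_id!r} has a single time point")
    if np.any(steps <= 0):
        raise DialectError(f"sample {sample_id!r} has duplicate time points")
    if np.max(steps) - np.min(steps) > _DT_TOL:
        raise DialectError(
            f"sample {sample_id!r} has a non-constant time step "
            f"(range {np.min(steps)}..{np.max(steps)})"
        )
    return float(steps[0])


def read_response_csv(path, dialect: str = "long") -> Dataset:
    """Read a response-curve CSV in the ``long`` or ``wide`` dialect.

    Curves are grouped by ``sample_id`` in order of first appearance and
    time-sorted; ``dt`` is inferred from the time column (long) or fixed at
    1 s (wide).
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(
        path, dtype={"sample_id": str, "class_label": str}, float_precision="round_trip"
    )
    if dialect == "long":
        missing = [c for c in _LONG_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"long dialect requires columns {missing}, not found in {path}")
        curves = []
        for sid in df["sample_id"].unique():
            sub = df[df["sample_id"] == sid]
            labels = sub["class_label"].unique()
            if len(labels) != 1:
                raise FormatError(f"sample {sid!r} carries multiple class labels: {list(labels)}")
            sensors = np.sort(sub["sensor"].unique())
            times = np.sort(sub["t"].unique())
            dt = _infer_dt(times, sid)
            mat = np.empty((len(sensors), len(times)))
            piv = sub.pivot_table(index="sensor", columns="t", values="value", sort=True)
            if piv.isna().any().any():
                raise FormatError(f"sample {sid!r}: missing (sensor, t) combinations")
            mat[:] = piv.to_numpy()
            curves.append(ResponseCurve(str(sid), str(labels[0]), mat, dt=dt))
        return Dataset(curves)
    # wide
    fixed = ["sample_id", "class_label", "sensor"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise FormatError(f"wide dialect requires columns {missing}, not found in {path}")
    vcols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
    if not vcols:
        raise FormatError("wide dialect requires value columns v1..vN")
    vcols = sorted(vcols, key=lambda c: int(c[1:]))
    curves = []
    for sid in df["sample_id"].unique():
        sub = df[df["sample_id"] == sid].sort_values("sensor")
        labels = sub["class_label"].unique()
        if len(labels) != 1:
            raise FormatError(f"sample {sid!r} carries multiple class labels: {list(labels)}")
        mat = sub[vcols].to_numpy(dtype=float)
        curves.append(ResponseCurve(str(sid), str(labels[0]), mat, dt=1.0))
    return Dataset(curves)


def write_response_csv(ds: Dataset, path, dialect: str = "long"):
    """Write a dataset to CSV; inverse of :func:`read_response_csv`.

    Values round-trip at full double precision (written with repr-style
    shortest representation).  The wide dialect requires ``dt == 1`` for every
    curve, since it stores no time column.
    """
    if not ds.curves:
        raise InsufficientDataError("refusing to write an empty dataset")
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    if dialect == "long":
        for c in ds.curves:
            times = c.times
            for s in range(c.n_sensors):
                for z in range(c.n_time):
                    rows.append(
                        (c.sample_id, c.class_label, s + 1, times[z], c.values[s, z])
                    )
        out = pd.DataFrame(rows, columns=_LONG_COLUMNS)
    else:
        for c in ds.curves:
            if abs(c.dt - 1.0) > _DT_TOL:
                raise DialectError(
                    f"wide dialect assumes dt = 1 s; curve {c.sample_id!r} has dt={c.dt}"
                )
            for s in range(c.n_sensors):
                rows.append((c.sample_id, c.class_label, s + 1, *c.values[s]))
        cols = ["sample_id", "class_label", "sensor"] + [
            f"v{z+1}" for z in range(ds.curves[0].n_time)
        ]
        out = pd.DataFrame(rows, columns=cols)
    # %.17g guarantees exact float64 round-trips through text
    out.to_csv(path, index=False, float_format="%.17g")
    return path
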