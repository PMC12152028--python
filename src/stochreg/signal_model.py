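"""Core data types for Bio-FET measurements and fitted quantities.

A measurement is a single, uniformly sampled, dimensionless time series
``X_{t_0}, ..., X_{t_M}``.  The denoising model treats it as a path of a
linear drift-diffusion SDE

    dX_t = [a0(t) + a1(t) X_t] dt + b(t) dW_t,

whose coefficients are estimated locally (see :mod:`stochreg.estimation`).
This module holds the containers shared by the whole pipeline plus CSV I/O
and dimensional/dimensionless conversion.  All internal computation is
dimensionless; characteristic scales are presentation-only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError, GridError

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids a circular import
    from .kernels import KernelSpec

#: Relative tolerance on |(t_{i+1}-t_i) - dt| for a grid to count as uniform.
GRID_RTOL = 1e-9


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled dimensionless time series.

    Parameters
    ----------
    times
        Strictly increasing grid ``t_0 .. t_M``.
    values
        Samples ``X_{t_0} .. X_{t_M}``.
    dt
        Uniform step.  Every successive difference must agree with ``dt``
        to within ``GRID_RTOL * dt``.
    char_time, char_value
        Characteristic scales used only by :func:`to_dimensional` /
        :func:`to_dimensionless`.
    """

    times: np.ndarray
    values: np.ndarray
    dt: float
    char_time: float = 1.0
    char_value: float = 1.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise FormatError("times and values must be one-dimensional")
        if times.size != values.size:
            raise FormatError(
                f"length mismatch: {times.size} times vs {values.size} values"
            )
        if times.size < 5:
            raise FormatError("a signal needs at least 5 samples (M >= 4)")
        if not np.isfinite(values).all():
            raise DataError("signal contains non-finite values")
        if not np.isfinite(times).all():
            raise DataError("time grid contains non-finite values")
        if self.dt <= 0:
            raise GridError(f"dt must be positive, got {self.dt}")
        diffs = np.diff(times)
        if np.max(np.abs(diffs - self.dt)) > GRID_RTOL * self.dt:
            raise GridError("time grid is not uniform with the stated dt")
        if self.char_time <= 0 or self.char_value <= 0:
            raise ValueError("characteristic scales must be positive")

    @property
    def n_increments(self) -> int:
        """Number of increments M (one less than the number of samples)."""
        return self.times.size - 1

    @property
    def duration(self) -> float:
        """Record length T = t_M - t_0."""
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class IncrementSeries:
    """First differences of a signal and their rates.

    ``increments[i] = X_{i+1} - X_i`` and ``rates[i] = increments[i] / dt``
    for ``i = 0 .. M-1``; ``anchors[i] = X_i`` is the state at the left node
    of increment ``i`` (the value at node i and the increment leaving it
    share the index i).
    """

    increments: np.ndarray
    rates: np.ndarray
    anchors: np.ndarray
    count: int
    dt: float


@dataclass(frozen=True)
class CoefficientEstimates:
    """Per-increment estimated SDE coefficients.

    ``a0[i]``, ``a1[i]`` are the local weighted-regression drift estimates
    and ``b[i] >= 0`` the local maximum-likelihood diffusion estimate for
    increment ``i``.  In the default windowed mode all three are piecewise
    constant on the window partition.  ``b`` is ``None`` until the
    diffusion stage has run.
    """

    a0: np.ndarray
    a1: np.ndarray
    b: Optional[np.ndarray]
    kernel: "KernelSpec"
    k: int

    def __post_init__(self) -> None:
        a0 = np.asarray(self.a0, dtype=float)
        a1 = np.asarray(self.a1, dtype=float)
        object.__setattr__(self, "a0", a0)
        object.__setattr__(self, "a1", a1)
        if a0.shape != a1.shape:
            raise ValueError("a0 and a1 must have identical shape")
        if self.b is not None:
            b = np.asarray(self.b, dtype=float)
            object.__setattr__(self, "b", b)
            if b.shape != a0.shape:
                raise ValueError("b must match the drift arrays in shape")
            if (b < 0).any():
                raise ValueError("diffusion estimates must be nonnegative")

    @property
    def count(self) -> int:
        return self.a0.size


def read_signal(
    path: str | Path,
    time_column: str = "time",
    value_column: str = "signal",
) -> Signal:
    """Read a measurement from a headered CSV file.

    The step ``dt`` is taken as the median of the successive time
    differences; non-uniform grids (beyond ``GRID_RTOL``) are rejected
    rather than resampled.  If a ``<path>.meta.json`` sidecar exists, its
    ``char_time`` / ``char_value`` entries are attached to the signal.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in (time_column, value_column):
        if col not in frame.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    if len(frame) < 5:
        raise FormatError(f"{path} has fewer than 5 rows")
    times = frame[time_column].to_numpy(dtype=float)
    values = frame[value_column].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DataError(f"{path} contains NaN or infinite signal values")
    diffs = np.diff(times)
    if (diffs <= 0).any():
        raise GridError(f"time column of {path} is not strictly increasing")
    dt = float(np.median(diffs))
    char_time, char_value = 1.0, 1.0
    sidecar = path.with_name(path.name + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        char_time = float(meta.get("char_time", 1.0))
        char_value = float(meta.get("char_value", 1.0))
    return Signal(times, values, dt, char_time=char_time, char_value=char_value)


def write_signal(
    s: Signal,
    path: str | Path,
    time_column: str = "time",
    value_column: str = "signal",
    sidecar: bool = False,
) -> None:
    """Write a signal as CSV (lossless to full double precision).

    With ``sidecar=True`` a ``<path>.meta.json`` file carrying the
    characteristic scales is written next to the CSV.
    """
    path = Path(path)
    frame = pd.DataFrame({time_column: s.times, value_column: s.values})
    frame.to_csv(path, index=False, float_format="%.17g")
    if sidecar:
        meta = {"char_time": s.char_time, "char_value": s.char_value}
        path.with_name(path.name + ".meta.json").write_text(
            json.dumps(meta, sort_keys=True)
        )


def to_dimensional(s: Signal) -> Signal:
    """Scale times by the characteristic time and values by the
    characteristic signal level.  Inverse of :func:`to_dimensionless`."""
    if s.char_time <= 0 or s.char_value <= 0:
        raise ValueError("characteristic scales must be positive")
    return Signal(
        s.times * s.char_time,
        s.values * s.char_value,
        s.dt * s.char_time,
        char_time=s.char_time,
        char_value=s.char_value,
    )


def to_dimensionless(s: Signal) -> Signal:
    """Undo :func:`to_dimensional` using the scales carried by the signal."""
    if s.char_time <= 0 or s.char_value <= 0:
        raise ValueError("characteristic scales must be positive")
    return Signal(
        s.times / s.char_time,
        s.values / s.char_value,
        s.dt / s.char_time,
        char_time=s.char_time,
        char_value=s.char_value,
    )


def increments(s: Signal) -> IncrementSeries:
    """First-difference view of a signal (M increments for M+1 samples)."""
    deltas = np.diff(s.values)
    return IncrementSeries(
        increments=deltas,
        rates=deltas / s.dt,
        anchors=s.values[:-1].copy(),
        count=s.n_increments,
        dt=s.dt,
    )
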