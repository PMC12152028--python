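"""Epanechnikov kernel variants and per-window weight vectors.

Three variants of the parabolic kernel ``(3/(4h))(1 - u^2)`` are used, with
the dimensionless offset ``u = (t_j - t_i)/h``:

* ``left``     — support ``-1 <= u < 0``: weights strictly historical points;
* ``right``    — support ``0 <= u < 1``: weights the center and future points;
* ``centered`` — support ``-1 <= u <= 1``.

The one-sided variants are used exactly as printed (mass 1/2, not
renormalized): the kernel mass cancels in both the drift and the diffusion
estimators, so renormalization would not change any estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateWindowError
from .signal_model import Signal

SIDES = ("left", "right", "centered")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel side plus bandwidth ``h = dt * k``."""

    side: str
    h: float

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"unknown kernel side {self.side!r}; use one of {SIDES}")
        if self.h <= 0:
            raise ValueError(f"bandwidth must be positive, got {self.h}")


@dataclass(frozen=True)
class WeightProfile:
    """Kernel weights of one window, centered on increment ``center_index``."""

    center_index: int
    weights: np.ndarray
    weight_sum: float


def kernel_value(u, side: str, h: float):
    """Evaluate the kernel at dimensionless offset(s) ``u``.

    Returns ``(3/(4h))(1 - u^2)`` on the side's support and 0 elsewhere.
    Support boundaries are exactly as printed: the left kernel is zero for
    ``0 <= u``, the right kernel for ``u < 0`` and ``1 <= u``.  Scalar in,
    scalar out; array in, array out.
    """
    if side not in SIDES:
        raise ValueError(f"unknown kernel side {side!r}; use one of {SIDES}")
    if h <= 0:
        raise ValueError(f"bandwidth must be positive, got {h}")
    u_arr = np.asarray(u, dtype=float)
    if side == "left":
        mask = (u_arr >= -1.0) & (u_arr < 0.0)
    elif side == "right":
        mask = (u_arr >= 0.0) & (u_arr < 1.0)
    else:
        mask = (u_arr >= -1.0) & (u_arr <= 1.0)
    out = np.where(mask, 0.75 / h * (1.0 - u_arr**2), 0.0)
    if np.isscalar(u) or np.ndim(u) == 0:
        return float(out)
    return out


def weight_profile(s: Signal, center: int, spec: KernelSpec) -> WeightProfile:
    """Kernel weights ``K_h((t_j - t_center)/h)`` over all increment anchors.

    ``center`` is an increment index (0-based, ``0 <= center < M``).  Weights
    are computed over the full range of increment indices with hard zeros
    outside the support, so the arithmetic is identical to the closed-form
    estimator sums.  Raises :class:`DegenerateWindowError` when the support
    contains no grid point (e.g. a left kernel centered at the first node).
    """
    m = s.n_increments
    if not 0 <= center < m:
        raise ValueError(f"center {center} outside increment range [0, {m})")
    anchor_times = s.times[:-1]
    u = (anchor_times - anchor_times[center]) / spec.h
    weights = kernel_value(u, spec.side, spec.h)
    weight_sum = float(np.sum(weights))
    if weight_sum <= 0.0:
        raise DegenerateWindowError(
            f"{spec.side} kernel at increment {center} has empty support "
            f"(h={spec.h})"
        )
    return WeightProfile(center_index=center, weights=weights, weight_sum=weight_sum)
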