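"""Local estimation of the SDE coefficients.

Drift: within each window the pair ``(a0, a1)`` minimizes the kernel-weighted
sum of squares

    sum_j ( dX_j/dt - a0 - a1 X_j )^2 K_h((t_j - t_i)/h),

i.e. an ordinary two-parameter weighted least squares with the kernel as
weight.  The normal equations are solved in anchor-centered coordinates
(x' = X - weighted mean), which is algebraically identical to the closed
forms but keeps the 2x2 system perfectly conditioned even when the window
barely moves.

Diffusion: the local weighted Gaussian log-likelihood of the normalized
residuals

    E_i = ( dX_i - [a0(i) + a1(i) X_i] dt ) / sqrt(dt)

is maximized by ``b(i)^2 = sum_j K_h(i,j) E_j^2 / S(i)`` with
``S(i) = sum_j K_h(i,j)``; ``b(i)`` is the square root of that weighted
mean square.  The drift term everywhere includes the state factor
(``a0 + a1*X``), the form the linear SDE model requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .kernels import KernelSpec, WeightProfile, weight_profile
from .signal_model import CoefficientEstimates, IncrementSeries, Signal, increments
from .windowing import WindowPartition, extend_signal, make_partition

logger = logging.getLogger(__name__)

#: Relative threshold on the weighted anchor variance below which the
#: two-parameter design is treated as singular.
SINGULAR_DESIGN_RTOL = 1e-12


@dataclass(frozen=True)
class ResidualSeries:
    """Normalized per-increment residuals E_i (one per increment)."""

    e_hat: np.ndarray


def fit_drift_window(data: IncrementSeries, w: WeightProfile) -> tuple[float, float]:
    """Weighted least-squares drift coefficients for one window.

    Falls back to ``a1 = 0`` with ``a0`` the weighted mean rate when the
    weighted variance of the anchors is below ``SINGULAR_DESIGN_RTOL`` times
    their weighted mean square (the minimizer restricted to the identifiable
    subspace); the fallback is logged.
    """
    wts = w.weights
    x = data.anchors
    y = data.rates
    sw = w.weight_sum
    mean_x = float(np.dot(wts, x)) / sw
    mean_y = float(np.dot(wts, y)) / sw
    xc = x - mean_x
    var_x = float(np.dot(wts, xc * xc)) / sw
    mean_sq = float(np.dot(wts, x * x)) / sw
    if var_x <= SINGULAR_DESIGN_RTOL * mean_sq or var_x == 0.0:
        logger.info(
            "singular drift design at increment %d (weighted anchor variance "
            "%.3e); falling back to intercept-only fit",
            w.center_index,
            var_x,
        )
        return mean_y, 0.0
    a1 = float(np.dot(wts, xc * (y - mean_y))) / (sw * var_x)
    a0 = mean_y - a1 * mean_x
    return a0, a1


def _drift_arrays(
    ext: Signal, spec: KernelSpec, part: WindowPartition
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window drift estimates broadcast over the padded increment range."""
    inc = increments(ext)
    m_ext = ext.n_increments
    a0 = np.empty(m_ext)
    a1 = np.empty(m_ext)
    for j, center in enumerate(part.window_centers):
        prof = weight_profile(ext, center, spec)
        a0_w, a1_w = fit_drift_window(inc, prof)
        sl = slice(2 * part.k * j, 2 * part.k * (j + 1))
        a0[sl] = a0_w
        a1[sl] = a1_w
    return a0, a1


def estimate_drift(
    s: Signal, spec: KernelSpec, part: WindowPartition
) -> CoefficientEstimates:
    """Windowed drift estimation over the whole record.

    The signal is linearly extended by ``part.r`` fictitious points before
    fitting; the returned arrays cover only the M real increments.
    """
    ext = extend_signal(s, part.r, tail_points=2 * part.k)
    a0, a1 = _drift_arrays(ext, spec, part)
    m = s.n_increments
    return CoefficientEstimates(a0=a0[:m], a1=a1[:m], b=None, kernel=spec, k=part.k)


def residuals(s: Signal, est: CoefficientEstimates) -> ResidualSeries:
    """Normalized residuals E_i = (dX_i - [a0(i)+a1(i) X_i] dt) / sqrt(dt)."""
    inc = increments(s)
    if est.count != inc.count:
        raise ValueError("estimates do not cover all increments")
    drift = (est.a0 + est.a1 * inc.anchors) * s.dt
    return ResidualSeries(e_hat=(inc.increments - drift) / np.sqrt(s.dt))


def fit_diffusion_window(res: ResidualSeries, w: WeightProfile) -> float:
    """Local maximum-likelihood diffusion estimate for one window.

    The maximizer of the weighted Gaussian log-likelihood is the square
    root of the kernel-weighted mean of the squared residuals.
    """
    return float(np.sqrt(np.dot(w.weights, res.e_hat**2) / w.weight_sum))


def estimate_diffusion(
    s: Signal,
    est: CoefficientEstimates,
    spec: KernelSpec,
    part: WindowPartition,
) -> CoefficientEstimates:
    """Windowed diffusion estimation; returns estimates with ``b`` filled.

    Residuals are computed on the extended record (reusing the drift values
    of each window, which are piecewise constant), and the fictitious
    increments are dropped from the result.
    """
    ext = extend_signal(s, part.r, tail_points=2 * part.k)
    first_member = 2 * part.k * part.member_map
    a0_ext = est.a0[np.minimum(first_member, est.count - 1)]
    a1_ext = est.a1[np.minimum(first_member, est.count - 1)]
    inc = increments(ext)
    drift = (a0_ext + a1_ext * inc.anchors) * ext.dt
    res = ResidualSeries(e_hat=(inc.increments - drift) / np.sqrt(ext.dt))
    m_ext = ext.n_increments
    b = np.empty(m_ext)
    for j, center in enumerate(part.window_centers):
        prof = weight_profile(ext, center, spec)
        b[2 * part.k * j : 2 * part.k * (j + 1)] = fit_diffusion_window(res, prof)
    m = s.n_increments
    return replace(est, b=b[:m])


def fit_coefficients(
    s: Signal, side: str, k: int, mode: str = "window"
) -> CoefficientEstimates:
    """Full coefficient estimation (drift then diffusion) for one bandwidth.

    ``mode="window"`` (default) computes one estimate per disjoint window
    and assigns it to all member increments.  ``mode="rolling"`` re-centers
    the kernel on every increment instead (a diagnostic mode; no padding is
    performed, so one-sided kernels can be degenerate near the boundary).
    """
    if mode == "window":
        part = make_partition(s.n_increments, k)
        spec = KernelSpec(side=side, h=s.dt * k)
        est = estimate_drift(s, spec, part)
        return estimate_diffusion(s, est, spec, part)
    if mode != "rolling":
        raise ValueError(f"unknown estimation mode {mode!r}")
    spec = KernelSpec(side=side, h=s.dt * k)
    inc = increments(s)
    m = s.n_increments
    a0 = np.empty(m)
    a1 = np.empty(m)
    for i in range(m):
        prof = weight_profile(s, i, spec)
        a0[i], a1[i] = fit_drift_window(inc, prof)
    res = ResidualSeries(e_hat=(inc.increments - (a0 + a1 * inc.anchors) * s.dt)
                         / np.sqrt(s.dt))
    b = np.empty(m)
    for i in range(m):
        prof = weight_profile(s, i, spec)
        b[i] = fit_diffusion_window(res, prof)
    return CoefficientEstimates(a0=a0, a1=a1, b=b, kernel=spec, k=k)
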