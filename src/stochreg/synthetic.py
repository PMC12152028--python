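"""Synthetic Bio-FET measurements across instrument aspect ratios.

The experimental streptavidin/biotin trace and the physical solution-well
transport model behind the original synthetic ensemble are not deposited,
so this module provides a documented surrogate: a monotone saturating
binding curve

    X_clean(t) = A * (1 - exp(-t / tau(eps))),   tau(eps) = tau_ref * eps,

whose equilibration time grows with the aspect ratio eps (instruments with
smaller wells equilibrate faster, because the injected reactant starts
closer to the gate), plus i.i.d. additive Gaussian noise N(mu_w, sigma_w^2)
on every sample.  The noise is added to curve samples — it is measurement
noise, not Brownian forcing — and the fitting pipeline is given no
knowledge of that.  A user-supplied curve function can replace the
exponential family.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

from .reference import ASPECT_RATIOS, EPSILON_MAX, EPSILON_MIN
from .signal_model import Signal


@dataclass(frozen=True)
class InstrumentSpec:
    """Parameters of one synthetic instrument/measurement.

    Defaults give a dimensionless record of M = 1200 unit steps saturating
    at amplitude 1 with noise standard deviation 2e-3 — a noise-to-plateau
    ratio at which the optimal reconstruction errors are of the same order
    as those reported for the experimental instrument.
    """

    epsilon: float
    amplitude: float = 1.0
    tau_ref: float = 80.0
    m: int = 1200
    dt: float = 1.0
    noise_mean: float = 0.0
    noise_sd: float = 2e-3
    seed: int = 0
    bounds: Optional[tuple] = (EPSILON_MIN, EPSILON_MAX)

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("aspect ratio must be positive")
        if self.bounds is not None:
            lo, hi = self.bounds
            if not lo <= self.epsilon <= hi:
                raise ValueError(
                    f"aspect ratio {self.epsilon} outside [{lo}, {hi}]; "
                    "pass bounds=None to override"
                )
        if self.amplitude <= 0 or self.tau_ref <= 0 or self.dt <= 0:
            raise ValueError("amplitude, tau_ref and dt must be positive")
        if self.m < 4:
            raise ValueError("need at least 4 increments")
        if self.noise_sd < 0:
            raise ValueError("noise standard deviation must be nonnegative")

    @property
    def tau(self) -> float:
        """Equilibration time constant tau_ref * epsilon."""
        return self.tau_ref * self.epsilon


CurveFn = Callable[[InstrumentSpec, np.ndarray], np.ndarray]


def _exponential_curve(spec: InstrumentSpec, t: np.ndarray) -> np.ndarray:
    return spec.amplitude * (1.0 - np.exp(-t / spec.tau))


def clean_curve(spec: InstrumentSpec, curve_fn: CurveFn | None = None) -> Signal:
    """Noise-free binding curve on the uniform grid of the instrument."""
    t = np.arange(spec.m + 1) * spec.dt
    fn = curve_fn or _exponential_curve
    return Signal(t, fn(spec, t), spec.dt)


def synthesize_measurement(
    spec: InstrumentSpec, curve_fn: CurveFn | None = None
) -> Signal:
    """Clean curve plus i.i.d. Gaussian noise, reproducible by seed."""
    clean = clean_curve(spec, curve_fn)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(spec.noise_mean, spec.noise_sd, size=spec.m + 1)
    return Signal(clean.times, clean.values + noise, spec.dt)


def reference_ensemble(
    curve_fn: CurveFn | None = None, **common
) -> list[tuple[float, Signal]]:
    """Ten synthetic measurements at the reference aspect ratios.

    Keyword arguments override the :class:`InstrumentSpec` defaults shared
    by all instruments; instrument ``i`` uses seed ``seed + i`` so every
    noise realization is distinct but the ensemble is reproducible.
    """
    base_seed = common.pop("seed", 0)
    out = []
    for i, eps in enumerate(ASPECT_RATIOS):
        spec = InstrumentSpec(epsilon=eps, seed=base_seed + i, **common)
        out.append((eps, synthesize_measurement(spec, curve_fn)))
    return out
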