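"""Euler-Maruyama reconstruction of the estimated signal.

With estimated coefficients the reconstruction steps

    Y_{i+1} = Y_i + [a0(i) + a1(i) Y_i] dt + b(i) dW_i,       Y_0 = X_0,

with dW_i ~ N(0, dt).  The deterministic component Y^(d) uses the same
drift on its own state and no noise; the stochastic component Y^(w) is the
cumulative sum of the noise increments b(i) dW_i, started at zero, using
the SAME Brownian draws as Y.  When the drift is state-independent
(a1 = 0) the decomposition Y = Y^(d) + Y^(w) is exact.

``drift_form="intercept_only"`` steps with drift (a0 + a1) dt instead — a
comparison mode that drops the state factor from the update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_model import CoefficientEstimates, Signal


@dataclass(frozen=True)
class Reconstruction:
    """Reconstructed path and its deterministic/stochastic split."""

    y: np.ndarray
    y_det: np.ndarray
    y_stoch: np.ndarray  # cumulative noise path, starts at 0
    dw: np.ndarray  # Brownian increments actually used
    seed: int

    @property
    def stoch_increments(self) -> np.ndarray:
        """Per-increment noise contributions b(i) dW_i."""
        return np.diff(self.y_stoch)


def brownian_increments(m: int, dt: float, seed: int) -> np.ndarray:
    """``m`` independent N(0, dt) draws, reproducible for a fixed seed."""
    if m < 1:
        raise ValueError("need at least one increment")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, np.sqrt(dt), size=m)


def reconstruct(
    s: Signal,
    est: CoefficientEstimates,
    seed: int,
    drift_form: str = "affine",
) -> Reconstruction:
    """Rebuild the signal from estimated coefficients by Euler-Maruyama."""
    m = s.n_increments
    if est.count != m:
        raise ValueError("estimates do not cover all increments")
    if est.b is None:
        raise ValueError("diffusion estimates missing; run the diffusion stage")
    if drift_form not in ("affine", "intercept_only"):
        raise ValueError(f"unknown drift_form {drift_form!r}")
    dt = s.dt
    dw = brownian_increments(m, dt, seed)
    noise = est.b * dw

    y = np.empty(m + 1)
    y_det = np.empty(m + 1)
    y[0] = y_det[0] = s.values[0]
    if drift_form == "affine":
        a0l = est.a0.tolist()
        a1l = est.a1.tolist()
        nl = noise.tolist()
        yv = float(s.values[0])
        yd = yv
        for i in range(m):
            a0i = a0l[i]
            a1i = a1l[i]
            yv = yv + (a0i + a1i * yv) * dt + nl[i]
            yd = yd + (a0i + a1i * yd) * dt
            y[i + 1] = yv
            y_det[i + 1] = yd
    else:
        drift = (est.a0 + est.a1) * dt
        y[1:] = s.values[0] + np.cumsum(drift + noise)
        y_det[1:] = s.values[0] + np.cumsum(drift)

    y_stoch = np.empty(m + 1)
    y_stoch[0] = 0.0
    y_stoch[1:] = np.cumsum(noise)
    return Reconstruction(y=y, y_det=y_det, y_stoch=y_stoch, dw=dw, seed=seed)
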