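import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "stochreg",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("stochreg")

from stochreg import Signal


def make_linear_signal(m=40, dt=1.0, intercept=2.0, slope=3.0):
    """Signal with exactly constant increment rates (affine with a1 = 0)."""
    t = np.arange(m + 1) * dt
    return Signal(t, intercept + slope * t, dt)


def make_affine_rate_signal(alpha=0.5, beta=-0.05, x0=0.0, m=48, dt=1.0):
    """Noise-free path of X_{i+1} = X_i + (alpha + beta X_i) dt.

    Every increment rate satisfies dX/dt = alpha + beta X exactly, so local
    weighted regression should recover (alpha, beta) in every window.
    """
    x = np.empty(m + 1)
    x[0] = x0
    for i in range(m):
        x[i + 1] = x[i] + (alpha + beta * x[i]) * dt
    return Signal(np.arange(m + 1) * dt, x, dt)


def simulate_linear_sde(a0, a1, b, m, dt, seed, x0=0.0):
    """Euler path of dX = (a0 + a1 X) dt + b dW with N(0, dt) increments."""
    rng = np.random.default_rng(seed)
    dw = rng.normal(0.0, np.sqrt(dt), m)
    x = np.empty(m + 1)
    x[0] = x0
    for i in range(m):
        x[i + 1] = x[i] + (a0 + a1 * x[i]) * dt + b * dw[i]
    return Signal(np.arange(m + 1) * dt, x, dt)


@pytest.fixture
def linear_signal():
    return make_linear_signal()


@pytest.fixture
def affine_rate_signal():
    return make_affine_rate_signal()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
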