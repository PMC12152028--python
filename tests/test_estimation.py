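import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from stochreg import (
    CoefficientEstimates,
    IncrementSeries,
    KernelSpec,
    Signal,
    WeightProfile,
    estimate_diffusion,
    estimate_drift,
    fit_coefficients,
    fit_diffusion_window,
    fit_drift_window,
    increments,
    make_partition,
    residuals,
    weight_profile,
)
from stochreg.estimation import ResidualSeries

from conftest import make_affine_rate_signal, simulate_linear_sde


def _series(anchors, rates, dt=1.0):
    anchors = np.asarray(anchors, float)
    rates = np.asarray(rates, float)
    return IncrementSeries(
        increments=rates * dt, rates=rates, anchors=anchors,
        count=anchors.size, dt=dt,
    )


def _profile(weights, center=0):
    weights = np.asarray(weights, float)
    return WeightProfile(center_index=center, weights=weights,
                         weight_sum=float(weights.sum()))


class TestFitDriftWindow:
    def test_recovers_exact_affine_relation(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        data = _series(x, 2.0 + 0.5 * x)
        a0, a1 = fit_drift_window(data, _profile(np.ones(5)))
        assert a0 == pytest.approx(2.0, abs=1e-12)
        assert a1 == pytest.approx(0.5, abs=1e-12)

    def test_constant_anchors_fall_back_to_intercept_only(self):
        data = _series(np.full(6, 5.0), np.zeros(6))
        a0, a1 = fit_drift_window(data, _profile(np.ones(6)))
        assert (a0, a1) == (0.0, 0.0)

    def test_fallback_uses_weighted_mean_rate(self):
        data = _series(np.full(4, 5.0), np.array([1.0, 2.0, 3.0, 4.0]))
        w = np.array([1.0, 1.0, 1.0, 2.0])
        a0, a1 = fit_drift_window(data, _profile(w))
        assert a1 == 0.0
        assert a0 == pytest.approx(np.dot(w, [1, 2, 3, 4]) / w.sum())

    def test_matches_generic_wls_solver(self, rng):
        # the closed-form solution equals a generic WLS fit on the same weights
        for _ in range(25):
            n = rng.integers(6, 40)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            w = rng.uniform(0.05, 1.0, size=n)
            a0, a1 = fit_drift_window(_series(x, y), _profile(w))
            ref = sm.WLS(y, sm.add_constant(x), weights=w).fit().params
            assert a0 == pytest.approx(ref[0], rel=1e-10, abs=1e-12)
            assert a1 == pytest.approx(ref[1], rel=1e-10, abs=1e-12)


class TestEstimateDrift:
    def test_exact_affine_rates_recovered_in_every_window(self):
        s = make_affine_rate_signal(alpha=0.5, beta=-0.05, m=48)
        part = make_partition(48, 4)
        est = estimate_drift(s, KernelSpec("centered", 4.0), part)
        np.testing.assert_allclose(est.a0, 0.5, rtol=1e-9)
        np.testing.assert_allclose(est.a1, -0.05, rtol=1e-9)

    def test_single_window_equals_global_weighted_fit(self, rng):
        m = 40
        t = np.arange(m + 1.0)
        s = Signal(t, rng.normal(size=m + 1).cumsum(), 1.0)
        k = m // 2
        part = make_partition(m, k)
        spec = KernelSpec("centered", float(k))
        est = estimate_drift(s, spec, part)
        prof = weight_profile(s, k, spec)
        inc = increments(s)
        mask = prof.weights > 0
        ref = sm.WLS(
            inc.rates[mask],
            sm.add_constant(inc.anchors[mask]),
            weights=prof.weights[mask],
        ).fit().params
        assert est.a0[0] == pytest.approx(ref[0], rel=1e-9)
        assert est.a1[0] == pytest.approx(ref[1], rel=1e-9)

    def test_estimates_piecewise_constant_on_windows(self, rng):
        m, k = 60, 5
        s = Signal(np.arange(m + 1.0), rng.normal(size=m + 1).cumsum(), 1.0)
        part = make_partition(m, k)
        est = estimate_drift(s, KernelSpec("centered", float(k)), part)
        for j in range(part.l):
            members = [i for i in part.members(j) if i < m]
            assert len(set(est.a0[members])) == 1
            assert len(set(est.a1[members])) == 1

    def test_affine_shift_invariance(self, rng):
        # X -> X + c maps (a0, a1) -> (a0 - a1 c, a1); fitted rates unchanged
        m, k, c = 48, 4, 13.7
        s = Signal(np.arange(m + 1.0), rng.normal(size=m + 1).cumsum(), 1.0)
        shifted = Signal(s.times, s.values + c, 1.0)
        part = make_partition(m, k)
        spec = KernelSpec("centered", float(k))
        est = estimate_drift(s, spec, part)
        est_c = estimate_drift(shifted, spec, part)
        np.testing.assert_allclose(est_c.a1, est.a1, rtol=1e-8)
        np.testing.assert_allclose(est_c.a0, est.a0 - est.a1 * c, rtol=1e-8)
        # diffusion estimates are also unchanged by the shift
        b = estimate_diffusion(s, est, spec, part).b
        b_c = estimate_diffusion(shifted, est_c, spec, part).b
        np.testing.assert_allclose(b_c, b, rtol=1e-7, atol=1e-12)


class TestResiduals:
    def test_exact_fit_leaves_zero_residuals(self):
        s = make_affine_rate_signal(alpha=0.5, beta=-0.05, m=48)
        est = fit_coefficients(s, "centered", 4)
        res = residuals(s, est)
        assert np.max(np.abs(res.e_hat)) < 1e-10

    def test_zero_coefficients_give_scaled_increments(self):
        s = make_affine_rate_signal(m=20, dt=0.25)
        est = CoefficientEstimates(
            np.zeros(20), np.zeros(20), None, KernelSpec("centered", 1.0), 4
        )
        res = residuals(s, est)
        np.testing.assert_allclose(
            res.e_hat, np.diff(s.values) / np.sqrt(0.25), rtol=1e-12
        )

    def test_pure_noise_residual_variance_matches_diffusion(self):
        # dX = b dW with zero drift estimates: Var(E) should be ~ b^2
        b, m, dt = 0.7, 4000, 0.1
        s = simulate_linear_sde(0.0, 0.0, b, m, dt, seed=42)
        est = CoefficientEstimates(
            np.zeros(m), np.zeros(m), None, KernelSpec("centered", 1.0), 4
        )
        var = np.var(residuals(s, est).e_hat)
        se = b**2 * np.sqrt(2.0 / m)
        assert abs(var - b**2) < 3 * se


class TestFitDiffusionWindow:
    def test_zero_residuals_give_zero(self):
        res = ResidualSeries(np.zeros(8))
        assert fit_diffusion_window(res, _profile(np.ones(8))) == 0.0

    def test_constant_residuals_give_their_magnitude(self, rng):
        res = ResidualSeries(np.full(8, -2.5))
        w = rng.uniform(0.1, 1.0, 8)
        assert fit_diffusion_window(res, _profile(w)) == pytest.approx(2.5)

    def test_doubling_residuals_doubles_estimate(self, rng):
        e = rng.normal(size=12)
        w = rng.uniform(0.1, 1.0, 12)
        b1 = fit_diffusion_window(ResidualSeries(e), _profile(w))
        b2 = fit_diffusion_window(ResidualSeries(2 * e), _profile(w))
        assert b2 == pytest.approx(2 * b1, rel=1e-12)

    def test_matches_numeric_likelihood_maximization(self, rng):
        # the closed form is the argmax of the local weighted log-likelihood
        def neg_loglik(b, e, w):
            return 0.5 * np.sum(w * (np.log(b**2) + e**2 / b**2))

        for _ in range(10):
            e = rng.normal(size=15)
            w = rng.uniform(0.05, 1.0, 15)
            b_hat = fit_diffusion_window(ResidualSeries(e), _profile(w))
            opt = minimize_scalar(
                neg_loglik, args=(e, w), bounds=(1e-4 * b_hat, 10 * b_hat),
                method="bounded", options={"xatol": 1e-14},
            )
            assert b_hat == pytest.approx(opt.x, rel=1e-6)


class TestEstimateDiffusion:
    def test_noise_free_signal_has_zero_diffusion(self):
        s = make_affine_rate_signal(m=48)
        est = fit_coefficients(s, "centered", 4)
        assert np.max(est.b) < 1e-10

    def test_diffusion_nonnegative_and_piecewise_constant(self, rng):
        m, k = 60, 5
        s = Signal(np.arange(m + 1.0), rng.normal(size=m + 1).cumsum(), 1.0)
        est = fit_coefficients(s, "centered", k)
        assert np.all(est.b >= 0)
        part = make_partition(m, k)
        for j in range(part.l):
            members = [i for i in part.members(j) if i < m]
            assert len(set(est.b[members])) == 1

    def test_constant_coefficient_recovery_improves_with_length(self):
        # bias of the window-median estimates shrinks as the record grows
        truth = dict(a0=1.0, a1=-0.5, b=0.3)
        errs = {}
        for m in (500, 2000, 8000):
            s = simulate_linear_sde(truth["a0"], truth["a1"], truth["b"],
                                    m, 0.5, seed=9, x0=2.0)
            est = fit_coefficients(s, "centered", 50)
            errs[m] = (
                abs(np.median(est.a0) - truth["a0"]),
                abs(np.median(est.a1) - truth["a1"]),
                abs(np.median(est.b) - truth["b"]),
            )
        for i in range(3):
            assert errs[8000][i] < errs[500][i]


class TestRollingMode:
    def test_rolling_estimates_match_window_fit_on_exact_signal(self):
        s = make_affine_rate_signal(alpha=0.5, beta=-0.05, m=48)
        est = fit_coefficients(s, "centered", 4, mode="rolling")
        np.testing.assert_allclose(est.a0, 0.5, rtol=1e-9)
        np.testing.assert_allclose(est.a1, -0.05, rtol=1e-9)
        assert np.max(est.b) < 1e-10

    def test_unknown_mode_rejected(self, linear_signal):
        with pytest.raises(ValueError):
            fit_coefficients(linear_signal, "centered", 4, mode="sliding")
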