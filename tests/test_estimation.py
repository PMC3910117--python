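"""Two-step estimator: finite differences, both regression steps, recovery."""

import math
import warnings

import numpy as np
import pytest

from cyclefit import (
    ModelParams,
    Profile,
    estimate_ode_params,
    estimate_sinusoid_coeffs,
    evaluate_model,
    finite_first_derivative,
    finite_second_derivative,
    fit_profile,
    model_to_ode,
)
from cyclefit.estimation import TooShortProfileError, _step1_design

from .conftest import make_profile


class TestFiniteDifferences:
    def test_constant_profile_has_zero_derivatives(self):
        p = Profile("g", np.ones(5))
        assert finite_first_derivative(p) == pytest.approx([0, 0, 0])
        assert finite_second_derivative(p) == pytest.approx([0, 0, 0])

    def test_exact_for_quadratics(self):
        t = np.arange(1.0, 6.0)
        p = Profile("g", t**2)
        assert finite_first_derivative(p) == pytest.approx([4, 6, 8])
        assert finite_second_derivative(p) == pytest.approx([2, 2, 2])

    def test_second_order_accuracy_on_sine(self):
        delta = 0.01
        t = delta * np.arange(1, 101)
        p = Profile("g", np.sin(t), delta=delta)
        assert np.max(np.abs(finite_first_derivative(p) - np.cos(t[1:-1]))) < delta**2
        assert np.max(np.abs(finite_second_derivative(p) + np.sin(t[1:-1]))) < delta**2

    def test_too_short_profile_is_rejected(self):
        with pytest.raises(TooShortProfileError):
            finite_first_derivative(Profile("g", [1.0, 2.0]))


class TestStepOne:
    def test_noise_free_recovery_within_one_percent(self):
        truth = ModelParams(alpha=-0.05, omega=1.2, a=1.0, b=0.4, c=0.02, d=1.0)
        ode_truth = model_to_ode(truth.alpha, truth.omega, truth.c, truth.d)
        prof = make_profile(truth, m=200, delta=0.05)
        est = estimate_ode_params(prof)
        assert est.as_array() == pytest.approx(ode_truth.as_array(), rel=0.01, abs=0.01)

    def test_linear_profile_gives_zero_coefficients(self):
        t = np.arange(1.0, 21.0)
        est = estimate_ode_params(Profile("g", 2 * t + 3))
        assert est.as_array() == pytest.approx([0, 0, 0, 0], abs=1e-9)

    def test_normal_equation_orthogonality(self, smooth_params, rng):
        prof = make_profile(smooth_params, m=30, noise_sd=0.3, seed=4)
        est = estimate_ode_params(prof)
        X, Y = _step1_design(prof)
        residual = Y - X @ est.as_array()
        assert X.T @ residual == pytest.approx(np.zeros(4), abs=1e-8)

    def test_error_shrinks_as_delta_squared(self):
        # halving delta should cut the step-1 error about fourfold
        truth = ModelParams(alpha=-0.1, omega=1.0, a=1.0, b=0.5, c=0.05, d=2.0)
        ode_truth = model_to_ode(truth.alpha, truth.omega, truth.c, truth.d).as_array()
        errors = {}
        for m, delta in ((100, 0.1), (200, 0.05)):
            est = estimate_ode_params(make_profile(truth, m=m, delta=delta))
            errors[delta] = np.linalg.norm(est.as_array() - ode_truth)
        ratio = errors[0.1] / errors[0.05]
        assert 3.0 < ratio < 5.5


class TestStepTwo:
    def test_exact_interpolation_of_pure_cosine(self):
        p = ModelParams(alpha=0, omega=math.pi / 2, a=1, b=0, c=0, d=0)
        prof = make_profile(p, m=8)
        a, b = estimate_sinusoid_coeffs(prof, alpha=0, omega=math.pi / 2, c=0, d=0)
        assert (a, b) == pytest.approx((1, 0), abs=1e-12)

    def test_self_consistent_recovery(self, rng):
        for _ in range(10):
            p = ModelParams(
                alpha=rng.uniform(-0.2, 0.1),
                omega=rng.uniform(0.3, 1.5),
                a=rng.uniform(-2, 2),
                b=rng.uniform(-2, 2),
                c=rng.uniform(-0.1, 0.1),
                d=rng.uniform(-1, 1),
            )
            prof = make_profile(p, m=30)
            a, b = estimate_sinusoid_coeffs(prof, p.alpha, p.omega, p.c, p.d)
            assert (a, b) == pytest.approx((p.a, p.b), abs=1e-8)

    def test_noise_coefficients_shrink_with_length(self, rng):
        # on pure noise the LS coefficients are O(1/sqrt(m)) in expectation
        sizes = (20, 2000)
        mags = {}
        for m in sizes:
            draws = []
            for _ in range(40):
                prof = Profile("g", rng.standard_normal(m))
                a, b = estimate_sinusoid_coeffs(prof, 0.0, 1.0, 0.0, 0.0)
                draws.append(math.hypot(a, b))
            mags[m] = np.mean(draws)
        assert mags[2000] < mags[20] / 3


class TestFitProfile:
    def test_noise_free_recovery_within_five_percent(self):
        truth = ModelParams(alpha=-0.1, omega=1.0, a=1.0, b=0.5, c=0.05, d=2.0)
        fit = fit_profile(make_profile(truth, m=100, delta=0.1))
        assert not fit.degenerate
        rel = np.abs(fit.params.as_array() - truth.as_array()) / np.abs(
            truth.as_array()
        )
        assert np.max(rel) < 0.05

    def test_residual_vanishes_at_dense_sampling(self, smooth_params):
        prof = make_profile(smooth_params, m=400, delta=0.025)
        fit = fit_profile(prof)
        assert fit.s1_sq < 1e-6 * np.sum(prof.values**2)

    def test_linear_profile_is_degenerate(self):
        t = np.arange(1.0, 21.0)
        fit = fit_profile(Profile("g", 2 * t + 3))
        assert fit.degenerate and fit.params is None

    def test_short_profile_warns(self, smooth_params):
        with pytest.warns(UserWarning, match="finite-difference"):
            fit_profile(make_profile(smooth_params, m=9))

    def test_two_step_residual_near_brute_force_optimum(self, smooth_params):
        # independent oracle: grid over (alpha, omega) with inner linear LS
        prof = make_profile(smooth_params, m=60, delta=0.25)
        x, t = prof.values, prof.times
        best = math.inf
        for alpha in np.linspace(-0.3, 0.1, 41):
            env = np.exp(alpha * t)
            for omega in np.linspace(0.1, 2.0, 96):
                D = np.column_stack(
                    [env * np.cos(omega * t), env * np.sin(omega * t), t, np.ones_like(t)]
                )
                resid = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
                best = min(best, float(resid @ resid))
        fit = fit_profile(prof)
        assert fit.s1_sq <= best + 1e-4 * np.sum(x**2)

    def test_fourth_order_stencil_reduces_coarse_grid_bias(self, smooth_params):
        # at omega*delta ~ 1.4 the three-point stencil's truncation bias
        # dominates; the five-point stencil must fit far closer
        p = ModelParams(alpha=-0.08, omega=1.4, a=1.2, b=0.8, c=0.05, d=0.3)
        prof = make_profile(p, m=18)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1_c2 = fit_profile(prof, stencil="central2").s1_sq
            s1_c4 = fit_profile(prof, stencil="central4").s1_sq
        assert s1_c4 < s1_c2 / 5
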