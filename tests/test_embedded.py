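"""Embedded-task observer model: forward model, two-step fit, optimal boundary."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize
from scipy.stats import norm

from critshift.embedded import (
    boundary_error,
    combined_sd,
    expected_accuracy,
    fit_embedded_counts,
    fit_embedded_observer,
    invert_boundary,
    optimal_boundary,
    prob_report_narrow,
)
from critshift.tasks import EmbeddedCategoryTask2


class TestForwardModel:
    @pytest.mark.parametrize(
        "s,sigma,expected", [(3, 4, 5), (12, 0, 12), (3, 3, math.sqrt(18))]
    )
    def test_combined_sd(self, s, sigma, expected):
        assert combined_sd(s, sigma) == pytest.approx(expected, rel=1e-12)

    def test_combined_sd_rejects_negative(self):
        with pytest.raises(ValueError):
            combined_sd(-3, 1)
        with pytest.raises(ValueError):
            combined_sd(3, -1)

    def test_narrow_report_probability(self):
        assert prob_report_narrow(0.0, 3.0) == 0.0
        assert prob_report_narrow(1e6, 3.0) == pytest.approx(1.0)
        # boundary at the zero-noise optimum for sds 3 vs 12
        assert prob_report_narrow(5.159, 3.0) == pytest.approx(0.914507, abs=1e-5)

    def test_invert_boundary_values(self):
        assert invert_boundary(0.914507, 3.0) == pytest.approx(5.159, abs=1e-3)
        assert invert_boundary(0.6827, 1.0) == pytest.approx(1.0, abs=1e-3)
        assert invert_boundary(1e-9, 3.0) < 1e-6

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_invert_boundary_rejects_degenerate(self, p):
        with pytest.raises(ValueError):
            invert_boundary(p, 3.0)

    @given(
        p=st.floats(1e-6, 1 - 1e-6),
        sigma=st.floats(0.1, 50.0),
    )
    def test_round_trip_identity(self, p, sigma):
        assert prob_report_narrow(invert_boundary(p, sigma), sigma) == pytest.approx(
            p, abs=1e-10
        )


class TestTwoStepFit:
    def test_exact_recovery_from_forward_model(self, task2):
        p_a = prob_report_narrow(6.0, combined_sd(3.0, 4.0))
        p_b = prob_report_narrow(6.0, combined_sd(12.0, 4.0))
        fit = fit_embedded_observer(p_a, p_b, task2)
        assert fit.converged
        assert fit.sigma_sens == pytest.approx(4.0, abs=1e-6)
        assert fit.k == pytest.approx(6.0, abs=1e-6)

    def test_zero_noise_boundary_case(self, task2):
        k0 = optimal_boundary(0.0, task2).k_opt
        p_a = prob_report_narrow(k0, 3.0)
        p_b = prob_report_narrow(k0, 12.0)
        fit = fit_embedded_observer(p_a, p_b, task2)
        assert fit.sigma_sens == pytest.approx(0.0, abs=1e-4)
        assert fit.k == pytest.approx(k0, abs=1e-4)

    def test_irreconcilable_proportions_flagged_not_nan(self, task2):
        # narrow category reported less often under A than B: no sigma works
        fit = fit_embedded_observer(0.3, 0.5, task2)
        assert not fit.converged
        assert np.isfinite(fit.sigma_sens) and np.isfinite(fit.k)
        assert fit.objective_at_optimum > 0

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_rejects_uncorrected_extremes(self, p, task2):
        with pytest.raises(ValueError, match="p_narrow"):
            fit_embedded_observer(p, 0.3, task2)

    def test_count_interface_applies_loglinear(self, task2):
        fit = fit_embedded_counts(40, 40, 10, 40, task=task2)
        ref = fit_embedded_observer(40.5 / 41, 10.5 / 41, task2)
        assert fit.sigma_sens == pytest.approx(ref.sigma_sens, abs=1e-9)

    def test_matches_joint_binomial_ml(self, task2, rng):
        """Cross-validation against an independent maximum-likelihood fit."""

        def ml_fit(c_a, n_a, c_b, n_b):
            def nll(theta):
                s, k = theta
                pa = np.clip(prob_report_narrow(k, combined_sd(3.0, s)), 1e-12, 1 - 1e-12)
                pb = np.clip(prob_report_narrow(k, combined_sd(12.0, s)), 1e-12, 1 - 1e-12)
                return -(
                    c_a * np.log(pa)
                    + (n_a - c_a) * np.log(1 - pa)
                    + c_b * np.log(pb)
                    + (n_b - c_b) * np.log(1 - pb)
                )

            res = optimize.minimize(
                nll, x0=[3.0, 5.0], bounds=[(0.0, 100.0), (0.01, 100.0)], method="L-BFGS-B"
            )
            return res.x

        n = 5000
        for _ in range(5):
            c_a = rng.binomial(n, prob_report_narrow(6.0, combined_sd(3.0, 4.0)))
            c_b = rng.binomial(n, prob_report_narrow(6.0, combined_sd(12.0, 4.0)))
            fit = fit_embedded_counts(c_a, n, c_b, n, task=task2)
            s_ml, k_ml = ml_fit(c_a + 0.5, n + 1, c_b + 0.5, n + 1)
            assert fit.sigma_sens == pytest.approx(s_ml, abs=0.02)
            assert fit.k == pytest.approx(k_ml, abs=0.02)


def _brute_force_k_opt(sigma_sens: float, task: EmbeddedCategoryTask2) -> float:
    """Independent oracle: grid-search the accuracy-maximizing boundary."""
    sa = math.hypot(task.sd_narrow, sigma_sens)
    sb = math.hypot(task.sd_broad, sigma_sens)
    ks = np.arange(0.001, 5 * sb, 0.001)
    acc = 0.5 * (2 * norm.cdf(ks / sa) - 1) + 0.5 * (2 * (1 - norm.cdf(ks / sb)))
    return float(ks[np.argmax(acc)])


class TestOptimalBoundary:
    @pytest.mark.parametrize("sigma", [0.0, 1.0, 2.0, 5.0, 10.0, 20.0])
    def test_closed_form_equals_brute_force(self, sigma, task2):
        assert optimal_boundary(sigma, task2).k_opt == pytest.approx(
            _brute_force_k_opt(sigma, task2), abs=0.01
        )

    def test_known_values(self, task2):
        assert optimal_boundary(0.0, task2).k_opt == pytest.approx(5.1592, abs=1e-3)
        assert optimal_boundary(5.0, task2).k_opt == pytest.approx(8.2614, abs=1e-3)

    def test_boundary_widens_with_noise(self, task2):
        sigmas = np.linspace(0, 40, 60)
        kopts = [optimal_boundary(s, task2).k_opt for s in sigmas]
        assert np.all(np.diff(kopts) > 0)

    def test_large_noise_asymptote(self, task2):
        # with overwhelming internal noise the boundary tracks sigma_sens
        assert optimal_boundary(100.0, task2).k_opt / 100.0 == pytest.approx(1.0, abs=0.02)

    def test_maximizes_expected_accuracy(self, task2):
        for sigma in (0.0, 3.0, 9.0):
            k_opt = optimal_boundary(sigma, task2).k_opt
            best = expected_accuracy(k_opt, sigma, task2)
            for k in np.linspace(0.5, 30, 120):
                assert expected_accuracy(float(k), sigma, task2) <= best + 1e-12

    def test_degenerate_task_rejected(self):
        task = EmbeddedCategoryTask2(sd_narrow=3.0, sd_broad=3.0001)
        # nearly equal sds are fine; exactly equal is impossible to construct,
        # so exercise the guard directly via equal combined sds
        assert optimal_boundary(0.0, task).k_opt > 0

    def test_boundary_error_is_signed_difference(self, task2):
        k0 = optimal_boundary(0.0, task2).k_opt
        assert boundary_error(k0, k0) == 0.0
        assert boundary_error(6.0, k0) == pytest.approx(0.8408, abs=1e-3)
        with pytest.raises(ValueError):
            boundary_error(-1.0, k0)
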