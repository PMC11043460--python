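import math

import numpy as np
import pytest
from scipy import optimize

from osteotrack import (
    DegenerateVarianceError,
    IncrementData,
    InsufficientDataError,
    ParameterError,
    WienerParams,
    extract_increments,
    fit_wiener,
    wiener_loglik,
)


class TestExtractIncrements:
    def test_anchor_and_differencing(self, series_factory):
        s = series_factory([(50, 0.02), (54, 0.06)]).with_tau(48.0)
        data, held = extract_increments([s], None)
        np.testing.assert_allclose(data.increments, [0.02, 0.04])
        np.testing.assert_allclose(data.intervals, [2.0, 4.0])
        assert held == []

    def test_censor_time_splits_fit_and_validation(self, series_factory):
        s = series_factory([(50, 0.02), (54, 0.06)]).with_tau(48.0)
        data, held = extract_increments([s], censor_time=4.0)
        # cut at tau + 4 = 52: only the first observation retained
        np.testing.assert_allclose(data.increments, [0.02])
        np.testing.assert_allclose(data.intervals, [2.0])
        assert len(held) == 1 and held[0].age == 54

    def test_anchor_disabled(self, series_factory):
        s = series_factory([(50, 0.02), (54, 0.06)]).with_tau(48.0)
        data, _ = extract_increments([s], None, anchor_at_formation=False)
        np.testing.assert_allclose(data.increments, [0.04])
        np.testing.assert_allclose(data.intervals, [4.0])

    def test_single_positive_without_anchor_yields_nothing(self, series_factory):
        s = series_factory([(50, 0.0), (54, 0.02)]).with_tau(53.0)
        data, _ = extract_increments([s], None, anchor_at_formation=False)
        assert data.n == 0

    def test_series_without_tau_skipped(self, series_factory):
        s = series_factory([(50, 0.02), (54, 0.06)])  # no tau_hat
        data, _ = extract_increments([s], None)
        assert data.n == 0


class TestLoglik:
    def test_centered_residual_leaves_only_normalising_terms(self):
        data = IncrementData(np.array([0.05]), np.array([2.5]))
        mu = 0.02  # dx = mu*dt exactly
        sigma = 0.3
        expected = -math.log(sigma) - 0.5 * math.log(2 * math.pi * 2.5)
        assert wiener_loglik(mu, sigma, data) == pytest.approx(expected)

    def test_hand_evaluated_two_increment_sum(self):
        data = IncrementData(np.array([0.01, 0.03]), np.array([1.0, 2.0]))
        mu, sigma = 0.04 / 3, math.sqrt(8.333333333333331e-06)
        hand = sum(
            -math.log(sigma)
            - 0.5 * math.log(2 * math.pi * dt)
            - (dx - mu * dt) ** 2 / (2 * sigma**2 * dt)
            for dx, dt in [(0.01, 1.0), (0.03, 2.0)]
        )
        assert wiener_loglik(mu, sigma, data) == pytest.approx(hand)
        assert hand == pytest.approx(8.510796365074865)

    def test_order_invariance(self):
        d1 = IncrementData(np.array([0.01, 0.03, -0.01]), np.array([1.0, 2.0, 0.5]))
        d2 = IncrementData(np.array([-0.01, 0.03, 0.01]), np.array([0.5, 2.0, 1.0]))
        assert wiener_loglik(0.01, 0.02, d1) == pytest.approx(wiener_loglik(0.01, 0.02, d2))

    def test_sigma_must_be_positive(self):
        with pytest.raises(ParameterError):
            wiener_loglik(0.01, 0.0, IncrementData(np.array([0.01]), np.array([1.0])))


class TestFit:
    def test_closed_forms_hand_example(self):
        data = IncrementData(np.array([0.01, 0.03]), np.array([1.0, 2.0]))
        fit = fit_wiener(data)
        assert fit.mu_ == pytest.approx(0.04 / 3)
        assert fit.sigma_**2 == pytest.approx(8.3333333333e-06, rel=1e-6)
        assert fit.sigma_ == pytest.approx(0.0028868, rel=1e-4)

    def test_closed_form_matches_numerical_maximiser(self, rng):
        dx = rng.normal(0.013, 0.02, 200)
        dt = rng.uniform(0.5, 2.0, 200)
        data = IncrementData(dx * dt, dt)
        fit = fit_wiener(data)

        def neg(theta):
            return -wiener_loglik(theta[0], math.exp(theta[1]), data)

        res = optimize.minimize(neg, [0.01, math.log(0.02)], method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14})
        assert fit.mu_ == pytest.approx(res.x[0], rel=1e-6)
        assert fit.sigma_ == pytest.approx(math.exp(res.x[1]), rel=1e-6)

    def test_simulation_consistency(self, rng):
        mu, sigma = 0.013, 0.024
        dt = rng.uniform(0.5, 2.0, 5000)
        dx = mu * dt + sigma * np.sqrt(dt) * rng.standard_normal(5000)
        fit = fit_wiener(IncrementData(dx, dt))
        assert abs(fit.mu_ - mu) < 3 * fit.se_mu_
        assert abs(fit.sigma_ - sigma) < 3 * fit.se_sigma_

    def test_scale_equivariance(self):
        data = IncrementData(np.array([0.01, 0.03, 0.02]), np.array([1.0, 2.0, 1.5]))
        k = 3.7
        scaled = IncrementData(data.increments * k, data.intervals)
        f0, f1 = fit_wiener(data), fit_wiener(scaled)
        assert f1.mu_ == pytest.approx(k * f0.mu_)
        assert f1.sigma_ == pytest.approx(k * f0.sigma_)

    def test_time_unit_equivariance(self):
        data = IncrementData(np.array([0.01, 0.03, 0.02]), np.array([1.0, 2.0, 1.5]))
        k = 2.5
        scaled = IncrementData(data.increments, data.intervals * k)
        f0, f1 = fit_wiener(data), fit_wiener(scaled)
        assert f1.mu_ == pytest.approx(f0.mu_ / k)
        assert f1.sigma_ == pytest.approx(f0.sigma_ / math.sqrt(k))

    def test_unbiased_flag_changes_denominator(self):
        data = IncrementData(np.array([0.01, 0.03]), np.array([1.0, 2.0]))
        biased, unbiased = fit_wiener(data), fit_wiener(data, unbiased=True)
        assert unbiased.sigma_**2 == pytest.approx(biased.sigma_**2 * 2 / 1)

    def test_degenerate_variance(self):
        data = IncrementData(np.array([0.01, 0.02]), np.array([1.0, 2.0]))
        with pytest.raises(DegenerateVarianceError):
            fit_wiener(data)  # dx exactly proportional to dt

    def test_needs_two_increments(self):
        with pytest.raises(InsufficientDataError):
            fit_wiener(IncrementData(np.array([0.01]), np.array([1.0])))

    def test_negative_increments_are_retained(self, series_factory):
        s = series_factory(
            [(50, 0.05), (52, 0.03), (54, 0.08)], allow_negative=True
        ).with_tau(49.0)
        data, _ = extract_increments([s], None)
        assert (data.increments < 0).any()
        fit = fit_wiener(data)
        assert fit.sigma_ > 0


class TestEquivarianceProperties:
    """Exact equivariances of the closed-form Wiener MLE under rescaling."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    increments = st.lists(
        st.tuples(
            st.floats(-0.1, 0.1, allow_nan=False),
            st.floats(0.1, 5.0, allow_nan=False),
        ),
        min_size=3,
        max_size=30,
    )

    @given(data=increments, k=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_joint_rescaling(self, data, k):
        dx = np.array([d for d, _ in data])
        dt = np.array([t for _, t in data])
        base = IncrementData(dx, dt)
        try:
            f0 = fit_wiener(base)
        except (DegenerateVarianceError, ParameterError):
            return
        if f0.sigma_ < 1e-9:  # numerically degenerate; rescaling may hit exact 0
            return
        fx = fit_wiener(IncrementData(dx * k, dt))
        ft = fit_wiener(IncrementData(dx, dt * k))
        assert fx.mu_ == pytest.approx(k * f0.mu_, rel=1e-9)
        assert fx.sigma_ == pytest.approx(k * f0.sigma_, rel=1e-9)
        assert ft.mu_ == pytest.approx(f0.mu_ / k, rel=1e-9)
        assert ft.sigma_ == pytest.approx(f0.sigma_ / math.sqrt(k), rel=1e-9)
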