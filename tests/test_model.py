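import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import invgauss, norm, weibull_min

from osteotrack import (
    ModelParams,
    PainThreshold,
    ParameterError,
    WeibullParams,
    WienerParams,
    conditional_survival,
    degeneration_density,
    model_survival_curve,
    mttoop,
    pain_threshold_from_ap,
    predicted_growth_band,
    survival_function,
    ttoop_density,
)
from osteotrack.model import integration_upper_limit


class TestMttoop:
    def test_cervical_published_estimate(self, cervical, cervical_threshold):
        # c/mu + a*Gamma(1+1/b) with the published cervical parameters
        val = mttoop(cervical_threshold, cervical)
        assert val == pytest.approx(54.11, abs=0.01)

    def test_lumbar_published_estimate(self, lumbar, lumbar_threshold):
        val = mttoop(lumbar_threshold, lumbar)
        assert round(val, 2) == 60.40

    def test_equals_integral_of_survival(self, lumbar, lumbar_threshold):
        closed = mttoop(lumbar_threshold, lumbar)
        upper = integration_upper_limit(lumbar_threshold, lumbar)
        by_quad, _ = integrate.quad(
            lambda t: survival_function(t, lumbar_threshold, lumbar), 0, upper,
            limit=400,
        )
        assert by_quad == pytest.approx(closed, rel=1e-3)

    def test_monotone_in_threshold_and_drift(self, lumbar):
        wb, wn = lumbar.weibull, lumbar.wiener
        vals_c = [mttoop(PainThreshold(c), lumbar) for c in (0.1, 0.2, 0.3, 0.5)]
        assert np.all(np.diff(vals_c) > 0)
        vals_mu = [
            mttoop(PainThreshold(0.2), ModelParams(wb, WienerParams(m, wn.sigma)))
            for m in (0.005, 0.01, 0.02, 0.04)
        ]
        assert np.all(np.diff(vals_mu) < 0)


class TestPainThreshold:
    def test_population_defaults(self):
        assert pain_threshold_from_ap(19.13).c == 0.52
        assert pain_threshold_from_ap(46.31).c == 0.22

    def test_unrounded_variant(self):
        assert pain_threshold_from_ap(46.31, rounded=False).c == pytest.approx(
            10 / 46.31
        )

    def test_limit_equal_to_diameter(self):
        assert pain_threshold_from_ap(10.0).c == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            pain_threshold_from_ap(-5.0)


class TestConditionalSurvival:
    def test_no_elapsed_time_is_certain_survival(self, lumbar, lumbar_threshold):
        assert conditional_survival(50.0, 50.0, lumbar_threshold, lumbar.wiener) == 1.0

    def test_long_horizon_is_certain_passage(self, lumbar, lumbar_threshold):
        assert conditional_survival(5000.0, 50.0, lumbar_threshold, lumbar.wiener) < 1e-9

    def test_matches_inverse_gaussian_survival(self, lumbar):
        thr = PainThreshold(0.22)
        m = thr.c / lumbar.wiener.mu
        lam = thr.c**2 / lumbar.wiener.sigma**2
        for s in (2.0, 8.0, m, 30.0):
            expected = invgauss.sf(s, m / lam, scale=lam)
            assert conditional_survival(50 + s, 50, thr, lumbar.wiener) == pytest.approx(
                expected, rel=1e-10
            )

    def test_small_sigma_does_not_overflow(self):
        wn = WienerParams(mu=0.01, sigma=1e-6)
        v = conditional_survival(60.0, 50.0, PainThreshold(0.2), wn)
        assert 0.0 <= v <= 1.0

    def test_t_before_tau_rejected(self, lumbar, lumbar_threshold):
        with pytest.raises(ParameterError):
            conditional_survival(49.0, 50.0, lumbar_threshold, lumbar.wiener)


class TestDensities:
    def test_degeneration_density_normalises_to_formation_probability(self, lumbar):
        # integral over x equals P(osteophyte exists at t) = Weibull CDF
        wb = lumbar.weibull
        for t in (30.0, 55.0):
            hi = lumbar.wiener.mu * t + 6 * lumbar.wiener.sigma * math.sqrt(t) + 0.05
            val, _ = integrate.quad(
                lambda x: degeneration_density(x, t, lumbar), -0.3, hi, limit=300
            )
            assert val == pytest.approx(
                weibull_min.cdf(t, wb.b, scale=wb.a), abs=1e-4
            )

    def test_degeneration_density_vanishes_before_formation_support(self, cervical):
        # steep shape (b ~ 5.7): essentially no formation mass below a/10
        t = cervical.weibull.a / 10
        val, _ = integrate.quad(
            lambda x: degeneration_density(x, t, cervical), -0.1, 0.2, limit=200
        )
        assert val < 1e-4

    def test_small_sigma_limit_change_of_variables(self):
        # as sigma -> 0, h(x|t) -> f(t - x/mu)/mu on 0 < x < mu t
        params = ModelParams(
            WeibullParams(a=54.9779, b=2.3443), WienerParams(mu=0.012836, sigma=1e-5)
        )
        wb, mu = params.weibull, params.wiener.mu
        t = 70.0
        for x in (0.1, 0.2, 0.3):
            expected = weibull_min.pdf(t - x / mu, wb.b, scale=wb.a) / mu
            assert degeneration_density(x, t, params) == pytest.approx(
                expected, rel=1e-3
            )

    def test_ttoop_density_integrates_to_one(self, lumbar, lumbar_threshold):
        upper = integration_upper_limit(lumbar_threshold, lumbar)
        val, _ = integrate.quad(
            lambda t: ttoop_density(t, lumbar_threshold, lumbar), 0, upper, limit=300
        )
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_vanishing_threshold_reduces_to_formation_density(self, lumbar):
        thr = PainThreshold(1e-6)
        wb = lumbar.weibull
        for t in (40.0, 55.0, 70.0):
            assert ttoop_density(t, thr, lumbar) == pytest.approx(
                weibull_min.pdf(t, wb.b, scale=wb.a), rel=1e-3
            )

    def test_cervical_bulk_mass_near_mean_onset(self, cervical, cervical_threshold):
        mean = mttoop(cervical_threshold, cervical)
        val, _ = integrate.quad(
            lambda t: ttoop_density(t, cervical_threshold, cervical),
            0.0, mean + 3 * 15.0, limit=300,
        )
        assert val > 0.9


class TestSurvival:
    def test_starts_at_one(self, lumbar, lumbar_threshold):
        assert survival_function(0.0, lumbar_threshold, lumbar) == 1.0

    def test_consistent_with_onset_density(self, lumbar, lumbar_threshold):
        for t in (40.0, 55.0, 70.0):
            g_cum, _ = integrate.quad(
                lambda s: ttoop_density(s, lumbar_threshold, lumbar), 0, t, limit=300
            )
            r = survival_function(t, lumbar_threshold, lumbar)
            assert r + g_cum == pytest.approx(1.0, abs=1e-4)

    def test_non_increasing_on_grid(self, cervical, cervical_threshold):
        grid = np.linspace(0.5, 100, 200)
        curve = model_survival_curve(grid, cervical_threshold, cervical)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert curve.survival[0] <= 1.0


class TestGrowthBand:
    def test_zero_elapsed_time_degenerate(self, cervical):
        band = predicted_growth_band([0.0], cervical.wiener)
        assert band["mean"][0] == 0.0
        assert band["lower"][0] == band["upper"][0] == 0.0

    def test_cervical_band_at_four_years(self, cervical):
        band = predicted_growth_band([4.0], cervical.wiener, coverage=0.95)
        assert band["mean"][0] == pytest.approx(0.0582212)
        half = band["upper"][0] - band["mean"][0]
        z = norm.ppf(0.975)
        assert half == pytest.approx(z * 0.0113259 * 2.0, rel=1e-9)
        assert half == pytest.approx(0.044396, abs=5e-6)

    def test_zero_coverage_collapses_to_mean(self, cervical):
        band = predicted_growth_band([1.0, 4.0], cervical.wiener, coverage=0.0)
        np.testing.assert_allclose(band["lower"], band["mean"])
        np.testing.assert_allclose(band["upper"], band["mean"])

    def test_invalid_coverage(self, cervical):
        with pytest.raises(ParameterError):
            predicted_growth_band([1.0], cervical.wiener, coverage=1.5)
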