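import math

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from dietrisk import DistributionSpec, Family, ValidationError, fit_mle

SPECS = [
    DistributionSpec.lognormal(-1.0, 0.8),
    DistributionSpec.weibull(1.7, 0.4),
    DistributionSpec.gamma(2.5, 4.0),
    DistributionSpec.exponential(3.0),
    DistributionSpec.gpd(0.3, 0.5, 0.2),
    DistributionSpec.gpd(-0.4, 1.0, 0.0),
]


class TestDensities:
    def test_exponential_pdf_at_zero(self):
        assert DistributionSpec.exponential(1.0).pdf(0.0) == pytest.approx(1.0)

    def test_gamma_shape_one_equals_exponential(self):
        lam = 2.3
        g = DistributionSpec.gamma(1.0, lam)
        e = DistributionSpec.exponential(lam)
        x = np.array([0.01, 0.4, 1.0, 3.3])
        np.testing.assert_allclose(g.pdf(x), e.pdf(x), rtol=1e-12)

    def test_standard_lognormal_pdf_at_one(self):
        val = DistributionSpec.lognormal(0.0, 1.0).pdf(1.0)
        assert val == pytest.approx(1.0 / math.sqrt(2 * math.pi), rel=1e-12)

    def test_out_of_support_density_is_zero(self):
        assert DistributionSpec.gamma(2.0, 1.0).pdf(-1.0) == 0.0
        assert DistributionSpec.gpd(0.2, 1.0, 0.5).pdf(0.2) == 0.0

    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: f"{s.family.value}{s.params}")
    def test_pdf_integrates_to_one(self, spec):
        lo, hi = spec.support()
        if not math.isfinite(hi):
            hi = float(spec.quantile(1 - 1e-10))
        total, _ = integrate.quad(spec.pdf, lo, hi, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestGpd:
    def test_cdf_zero_at_threshold(self):
        for xi in (-0.3, 0.0, 0.7):
            assert DistributionSpec.gpd(xi, 1.3, 2.0).cdf(2.0) == 0.0

    def test_exponential_limit_median(self):
        assert DistributionSpec.gpd(0.0, 1.0, 0.0).cdf(math.log(2)) == pytest.approx(0.5)

    def test_closed_form_cdf(self):
        # 1 - (1 + 0.5*2)^(-2) = 0.75
        assert DistributionSpec.gpd(0.5, 1.0, 0.0).cdf(2.0) == pytest.approx(0.75)

    def test_quantile_exponential_limit(self):
        assert DistributionSpec.gpd(0.0, 1.0, 0.0).quantile(0.75) == pytest.approx(
            math.log(4)
        )

    def test_negative_shape_bounded_support(self):
        spec = DistributionSpec.gpd(-0.5, 1.0, 0.0)
        endpoint = 2.0  # u - sigma/xi
        assert spec.cdf(endpoint + 1.0) == 1.0
        assert spec.quantile(0.999999) <= endpoint + 1e-9

    @pytest.mark.parametrize("xi", [1e-9, -1e-9])
    def test_continuity_at_xi_zero(self, xi):
        limit = DistributionSpec.gpd(0.0, 1.0, 0.0)
        near = DistributionSpec.gpd(xi, 1.0, 0.0)
        x = np.array([0.1, 0.7, 2.0, 5.0])
        np.testing.assert_allclose(near.cdf(x), limit.cdf(x), atol=1e-6)
        np.testing.assert_allclose(
            near.quantile([0.1, 0.5, 0.9]), limit.quantile([0.1, 0.5, 0.9]), rtol=1e-6
        )

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValidationError):
            DistributionSpec.gpd(0.1, -1.0, 0.0)


class TestQuantiles:
    def test_lognormal_median(self):
        assert DistributionSpec.lognormal(1.3, 0.4).quantile(0.5) == pytest.approx(
            math.exp(1.3)
        )

    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: f"{s.family.value}{s.params}")
    def test_cdf_quantile_roundtrip(self, spec):
        ps = np.array([0.01, 0.1, 0.5, 0.9, 0.99, 0.999])
        np.testing.assert_allclose(spec.cdf(spec.quantile(ps)), ps, rtol=1e-9)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_out_of_range_p_rejected(self, p):
        with pytest.raises(ValidationError):
            DistributionSpec.exponential(1.0).quantile(p)

    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: f"{s.family.value}{s.params}")
    def test_cdf_monotone_and_limits(self, spec):
        lo, hi = spec.support()
        grid = np.asarray(spec.quantile(np.linspace(0.001, 0.999, 50)))
        vals = np.asarray(spec.cdf(grid))
        assert np.all(np.diff(vals) >= -1e-12)
        assert spec.cdf(lo) <= 1e-12
        big = hi if math.isfinite(hi) else float(spec.quantile(1 - 1e-12))
        assert spec.cdf(big) >= 1.0 - 1e-9


class TestFitMle:
    def test_lognormal_closed_form(self):
        data = [math.e ** 0, math.e ** 1, math.e ** 2]
        fit = fit_mle(data, "lognormal")
        assert fit.spec.param("log_mean") == pytest.approx(1.0)
        assert fit.spec.param("log_sd") == pytest.approx(math.sqrt(2.0 / 3.0))

    def test_exponential_closed_form(self, rng):
        data = rng.exponential(2.0, size=40)
        fit = fit_mle(data, "exponential")
        assert fit.spec.param("rate") == pytest.approx(1.0 / data.mean(), rel=1e-12)

    def test_gamma_parameter_recovery(self):
        # oracle: an independent optimizer on the same likelihood must not
        # beat our closed-equation solution
        data = DistributionSpec.gamma(2.0, 3.0).sample(5000, seed=99)
        fit = fit_mle(data, "gamma")
        assert fit.spec.param("shape") == pytest.approx(2.0, abs=0.15)
        assert fit.spec.param("rate") == pytest.approx(3.0, abs=0.25)

        def nll(theta):
            a, r = np.exp(theta)
            return -np.sum(DistributionSpec.gamma(a, r).logpdf(data))

        res = optimize.minimize(nll, x0=[0.0, 0.0], method="Nelder-Mead")
        assert fit.loglik >= -res.fun - 1e-6

    def test_weibull_matches_scipy_mle(self, rng):
        data = rng.weibull(1.5, size=500) * 2.0
        fit = fit_mle(data, "weibull")
        c, loc, scale = stats.weibull_min.fit(data, floc=0)
        assert fit.spec.param("shape") == pytest.approx(c, rel=1e-4)
        assert fit.spec.param("scale") == pytest.approx(scale, rel=1e-4)

    def test_lognormal_scale_equivariance(self, rng):
        data = np.exp(rng.normal(0.3, 0.7, 200))
        base = fit_mle(data, "lognormal")
        scaled = fit_mle(10.0 * data, "lognormal")
        assert scaled.spec.param("log_mean") == pytest.approx(
            base.spec.param("log_mean") + math.log(10), rel=1e-10
        )
        assert scaled.spec.param("log_sd") == pytest.approx(
            base.spec.param("log_sd"), rel=1e-10
        )

    def test_information_criteria_formulas(self, rng):
        data = rng.gamma(2.0, 1.0, 50)
        fit = fit_mle(data, "gamma")
        assert fit.k == 2
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)
        assert fit.bic == pytest.approx(fit.k * math.log(fit.n) - 2 * fit.loglik)

    def test_k_per_family(self, rng):
        data = rng.gamma(2.0, 1.0, 60)
        ks = {fam: fit_mle(data, fam).k for fam in ("lognormal", "weibull", "gamma", "exponential")}
        assert ks == {"lognormal": 2, "weibull": 2, "gamma": 2, "exponential": 1}

    @pytest.mark.parametrize("bad", [[], [1.0, -2.0, 3.0], [0.0, 1.0, 2.0], [1.0, 2.0]])
    def test_invalid_data_rejected(self, bad):
        with pytest.raises(ValidationError):
            fit_mle(bad, "lognormal")


class TestSampling:
    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: f"{s.family.value}{s.params}")
    def test_seed_determinism(self, spec):
        a = spec.sample(100, seed=7)
        b = spec.sample(100, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_sample_within_support(self):
        spec = DistributionSpec.gpd(-0.4, 1.0, 0.5)
        draws = spec.sample(10_000, seed=3)
        lo, hi = spec.support()
        assert draws.min() >= lo
        assert draws.max() <= hi

    def test_invalid_params_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            DistributionSpec.lognormal(0.0, -1.0)
        with pytest.raises(ValidationError):
            DistributionSpec.gamma(-1.0, 1.0)
        with pytest.raises(ValidationError):
            DistributionSpec.exponential(0.0)
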