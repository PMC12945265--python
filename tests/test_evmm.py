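import math

import numpy as np
import pytest
from scipy import integrate, optimize

from dietrisk import DistributionSpec, EvmmSpec, ValidationError, evmm_fit


class TestSpecMath:
    def test_cdf_continuous_at_threshold(self, lognormal_gpd_spec):
        u = lognormal_gpd_spec.threshold
        below = lognormal_gpd_spec.cdf(u - 1e-12)
        at = lognormal_gpd_spec.cdf(u)
        assert abs(below - at) < 1e-12
        assert at == pytest.approx(lognormal_gpd_spec.bulk.cdf(u))

    def test_normalization(self, lognormal_gpd_spec):
        assert lognormal_gpd_spec.cdf(1e12) == pytest.approx(1.0, abs=1e-9)
        assert lognormal_gpd_spec.cdf(1e-12) == pytest.approx(0.0, abs=1e-9)

    def test_bulk_based_tail_fraction(self, lognormal_gpd_spec):
        u = lognormal_gpd_spec.threshold
        hu = float(lognormal_gpd_spec.bulk.cdf(u))
        # P(X >= u) must equal 1 - H(u) exactly: no free tail fraction
        assert 1.0 - lognormal_gpd_spec.cdf(u) == pytest.approx(1.0 - hu, rel=1e-12)

    def test_quantile_matches_numeric_root(self):
        bulk = DistributionSpec.lognormal(0.0, 1.0)
        u = float(bulk.quantile(0.90))
        spec = EvmmSpec(bulk=bulk, threshold=u, tail_shape=0.2, tail_scale=0.5)
        for p in (0.5, 0.89, 0.95, 0.999):
            q = spec.quantile(p)
            # independent oracle: root-find the CDF itself
            root = optimize.brentq(lambda x: spec.cdf(x) - p, 1e-9, 1e6)
            assert q == pytest.approx(root, rel=1e-7)
            assert spec.cdf(q) == pytest.approx(p, rel=1e-9)

    def test_negative_tail_shape_respects_endpoint(self):
        bulk = DistributionSpec.gamma(2.0, 2.0)
        u = float(bulk.quantile(0.9))
        spec = EvmmSpec(bulk=bulk, threshold=u, tail_shape=-0.5, tail_scale=0.4)
        endpoint = spec.upper_endpoint()
        assert endpoint == pytest.approx(u + 0.8)
        assert spec.quantile(0.999999) <= endpoint + 1e-9

    def test_pdf_integrates_to_one(self, lognormal_gpd_spec):
        total, _ = integrate.quad(
            lognormal_gpd_spec.pdf, 0, float(lognormal_gpd_spec.quantile(1 - 1e-9)),
            limit=300, points=[lognormal_gpd_spec.threshold],
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_invalid_specs_rejected(self):
        bulk = DistributionSpec.lognormal(0.0, 1.0)
        with pytest.raises(ValidationError):
            EvmmSpec(bulk=bulk, threshold=1.0, tail_shape=0.1, tail_scale=-1.0)
        with pytest.raises(ValidationError):
            EvmmSpec(bulk=bulk, threshold=0.0, tail_shape=0.1, tail_scale=1.0)

    def test_free_tail_fraction_variant(self):
        bulk = DistributionSpec.lognormal(0.0, 1.0)
        u = float(bulk.quantile(0.9))
        spec = EvmmSpec(bulk=bulk, threshold=u, tail_shape=0.2, tail_scale=0.5,
                        tail_fraction=0.25)
        assert 1.0 - spec.cdf(u) == pytest.approx(0.25, rel=1e-12)
        assert spec.cdf(1e12) == pytest.approx(1.0, abs=1e-9)
        assert abs(spec.cdf(u - 1e-12) - spec.cdf(u)) < 1e-10


class TestSampling:
    def test_seed_determinism(self, lognormal_gpd_spec):
        a = lognormal_gpd_spec.sample(1000, seed=5)
        b = lognormal_gpd_spec.sample(1000, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_exceedance_fraction_binomial(self, lognormal_gpd_spec):
        n = 100_000
        draws = lognormal_gpd_spec.sample(n, seed=8)
        p_tail = 1.0 - float(lognormal_gpd_spec.bulk.cdf(lognormal_gpd_spec.threshold))
        observed = np.mean(draws >= lognormal_gpd_spec.threshold)
        sd = math.sqrt(p_tail * (1 - p_tail) / n)
        assert abs(observed - p_tail) < 3 * sd

    def test_sample_mean_matches_numeric_integral(self, lognormal_gpd_spec):
        # xi = 0.4 < 1 so the mean is finite; oracle is numeric integration
        mean_num = integrate.quad(
            lambda x: x * lognormal_gpd_spec.pdf(x),
            0, float(lognormal_gpd_spec.quantile(1 - 1e-10)),
            limit=400, points=[lognormal_gpd_spec.threshold],
        )[0]
        draws = lognormal_gpd_spec.sample(1_000_000, seed=17)
        assert draws.mean() == pytest.approx(mean_num, rel=0.01)

    def test_ecdf_close_to_cdf(self, lognormal_gpd_spec):
        # DKW bound at alpha = 0.01
        n = 200_000
        draws = np.sort(lognormal_gpd_spec.sample(n, seed=33))
        ecdf = np.arange(1, n + 1) / n
        gap = np.max(np.abs(ecdf - lognormal_gpd_spec.cdf(draws)))
        bound = math.sqrt(math.log(2 / 0.01) / (2 * n))
        assert gap < bound


class TestFit:
    def test_parameter_recovery_single_seed(self, lognormal_gpd_spec):
        data = lognormal_gpd_spec.sample(2000, seed=42)
        fit = evmm_fit(data, "lognormal")
        assert fit.converged
        assert fit.spec.tail_shape == pytest.approx(0.4, abs=0.2)
        assert fit.k == 5
        assert fit.n_exceedances == int(np.sum(data >= fit.spec.threshold))
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)
        assert fit.bic == pytest.approx(fit.k * math.log(fit.n) - 2 * fit.loglik)

    def test_loglik_beats_profile_grid_oracle(self, lognormal_gpd_spec):
        # oracle: direct likelihood evaluation of the generating spec
        data = lognormal_gpd_spec.sample(1500, seed=6)
        fit = evmm_fit(data, "lognormal")
        truth_ll = _joint_loglik(lognormal_gpd_spec, data)
        assert fit.loglik >= truth_ll - 1e-6

    def test_self_consistency_loglik_per_obs(self, lognormal_gpd_spec):
        data = lognormal_gpd_spec.sample(10_000, seed=9)
        fit = evmm_fit(data, "lognormal")
        truth_ll = _joint_loglik(lognormal_gpd_spec, data) / data.size
        assert fit.loglik / data.size == pytest.approx(truth_ll, abs=abs(truth_ll) * 0.02 + 0.02)

    def test_degenerate_uniform_data_with_forced_threshold(self, rng):
        data = rng.uniform(0.01, 1.0, 300)
        fit = evmm_fit(data, "gamma", threshold_grid=(90.0,), refine=False)
        assert fit.converged
        assert np.isfinite(fit.loglik)

    def test_too_few_exceedances_raises(self, rng):
        data = rng.gamma(2.0, 1.0, 30)
        from dietrisk import FitError

        with pytest.raises(FitError):
            evmm_fit(data, "gamma", threshold_grid=(99.9,), min_exceedances=5,
                     refine=False)

    @pytest.mark.parametrize("bad", [np.ones(5), -np.ones(20)])
    def test_invalid_data_rejected(self, bad):
        with pytest.raises(ValidationError):
            evmm_fit(bad, "lognormal")


def _joint_loglik(spec: EvmmSpec, data: np.ndarray) -> float:
    """Independent evaluation of the spliced likelihood (used as an oracle)."""
    u = spec.threshold
    below = data[data < u]
    exc = data[data >= u]
    hu = float(spec.bulk.cdf(u))
    ll = float(np.sum(spec.bulk.logpdf(below)))
    ll += exc.size * math.log1p(-hu)
    gpd = DistributionSpec.gpd(spec.tail_shape, spec.tail_scale, 0.0)
    ll += float(np.sum(gpd.logpdf(exc - u)))
    return ll
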