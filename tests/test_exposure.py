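import math

import numpy as np
import pytest

from dietrisk import (
    ConcentrationDataset,
    ConsumptionModel,
    DemographicGroup,
    DistributionSpec,
    ExposureDistribution,
    ValidationError,
    compute_edi,
    consumption_from_percentiles,
    read_concentration_csv,
    read_demographics,
    simulate_concentration,
    simulate_exposure,
)


class TestConcentrationDataset:
    def make(self):
        values = np.array([0.2, np.nan, 0.5, np.nan, 1.1, 0.08])
        detected = np.array([True, False, True, False, True, True])
        return ConcentrationDataset("DEHP", values, detected, lod=0.10)

    def test_detection_rate(self):
        ds = self.make()
        assert ds.n_total == 6
        assert ds.n_detected == 4
        assert ds.detection_rate == pytest.approx(4 / 6)

    def test_positives(self):
        np.testing.assert_allclose(self.make().positives, [0.2, 0.5, 1.1, 0.08])

    def test_between_lod_and_loq_values_kept(self):
        # 0.08 < LOD 0.10 is stored as given, not rejected
        assert 0.08 in self.make().positives

    def test_resample_preserves_status_pairs(self, rng):
        ds = self.make()
        boot = ds.resample(rng)
        assert boot.n_total == ds.n_total
        # every detected row must carry a value drawn from the original positives
        assert set(np.round(boot.positives, 6)) <= set(np.round(ds.positives, 6))

    def test_csv_roundtrip(self, tmp_path):
        ds = self.make()
        path = tmp_path / "conc.csv"
        ds.to_frame().to_csv(path, index=False)
        loaded = read_concentration_csv(path)["DEHP"]
        assert loaded.n_detected == ds.n_detected
        np.testing.assert_allclose(loaded.positives, ds.positives)
        assert loaded.lod == ds.lod

    def test_invalid_lod_rejected(self):
        with pytest.raises(ValidationError):
            ConcentrationDataset("X", np.array([1.0]), np.array([True]), lod=0.0)


class TestConsumption:
    def test_exact_two_point_inversion(self):
        m = consumption_from_percentiles(
            [(0.5, math.e ** 3), (0.975, math.e ** (3 + 1.959963984540054 * 0.5))]
        )
        assert m.log_mean == pytest.approx(3.0, abs=1e-9)
        assert m.log_sd == pytest.approx(0.5, abs=1e-6)

    def test_survey_style_triple(self):
        m = consumption_from_percentiles([(0.50, 51.3), (0.75, 88.8), (0.95, 140.6)])
        assert m.quantile(0.5) == pytest.approx(51.3, rel=0.15)

    def test_roundtrip_refit(self):
        m = ConsumptionModel(3.2, 0.45)
        targets = [(p, m.quantile(p)) for p in (0.25, 0.5, 0.75, 0.95)]
        refit = consumption_from_percentiles(targets)
        assert refit.log_mean == pytest.approx(3.2, abs=1e-9)
        assert refit.log_sd == pytest.approx(0.45, abs=1e-9)

    def test_non_monotone_targets_rejected(self):
        with pytest.raises(ValidationError):
            consumption_from_percentiles([(0.5, 60.0), (0.95, 50.0)])

    def test_median_of_draws(self):
        m = ConsumptionModel(3.0, 0.6)
        draws = m.sample(1_000_000, seed=13)
        assert np.median(draws) == pytest.approx(math.exp(3.0), rel=0.005)

    def test_small_log_sd_limit(self):
        m = ConsumptionModel(2.0, 1e-6)
        draws = m.sample(1000, seed=1)
        np.testing.assert_allclose(draws, math.exp(2.0), rtol=1e-4)

    def test_truncation_respected(self):
        m = ConsumptionModel(3.0, 0.6, lower=10.0, upper=50.0)
        draws = m.sample(20_000, seed=2)
        assert draws.min() >= 10.0
        assert draws.max() <= 50.0

    def test_negligible_truncation_mass_rejected(self):
        m = ConsumptionModel(3.0, 0.1, lower=1000.0, upper=1001.0)
        with pytest.raises(ValidationError):
            m.sample(10, seed=0)


class TestSimulateConcentration:
    def test_full_detection_uses_model_only(self):
        spec = DistributionSpec.lognormal(1.0, 0.1)  # support far above LOD
        draws = simulate_concentration(spec, 1.0, 0.1, 5000, seed=3)
        assert draws.min() > 0.5

    def test_zero_detection_is_uniform_below_lod(self):
        spec = DistributionSpec.lognormal(0.0, 1.0)
        draws = simulate_concentration(spec, 0.0, 0.10, 100_000, seed=4)
        assert draws.max() < 0.10
        assert draws.mean() == pytest.approx(0.05, rel=0.02)

    def test_zero_inflated_mean_closed_form(self):
        spec = DistributionSpec.lognormal(-1.0, 0.5)
        p, lod, n = 0.55, 0.10, 10_000
        draws = simulate_concentration(spec, p, lod, n, seed=5)
        m_pos = spec.mean()
        expected = p * m_pos + (1 - p) * lod / 2
        # 3 Monte Carlo sd of the simulated mean
        var = (
            p * (math.exp(0.25) * math.exp(-2 + 0.25) - 0.0)  # E[X^2] pos part
            + (1 - p) * lod ** 2 / 3
            - expected ** 2
            + p * 0.0
        )
        sim_sd = math.sqrt(abs(var) / n)
        assert abs(draws.mean() - expected) < 3 * sim_sd

    def test_determinism(self):
        spec = DistributionSpec.gamma(2.0, 4.0)
        np.testing.assert_array_equal(
            simulate_concentration(spec, 0.3, 0.05, 100, seed=6),
            simulate_concentration(spec, 0.3, 0.05, 100, seed=6),
        )

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValidationError):
            simulate_concentration(DistributionSpec.exponential(1.0), 1.2, 0.1, 10)


class TestEdi:
    def test_unit_arithmetic(self):
        np.testing.assert_allclose(compute_edi([100.0], [0.5], 50.0), [1.0])

    def test_zero_concentration(self):
        np.testing.assert_allclose(compute_edi([120.0], [0.0], 60.0), [0.0])

    def test_mean_product_of_independent_means(self):
        group = DemographicGroup("g", "18-49", "male", 60.0, ConsumptionModel(4.0, 0.5))
        spec = DistributionSpec.lognormal(-1.0, 0.8)
        expo = simulate_exposure(spec, 0.6, 0.1, group, "X", n_sim=200_000, seed=8)
        expected = (
            math.exp(4.0 + 0.125) * (0.6 * spec.mean() + 0.4 * 0.05) / 60.0
        )
        assert expo.summary()["mean"] == pytest.approx(expected, rel=0.02)

    def test_independence_of_streams(self):
        group = DemographicGroup("g", "18-49", "male", 60.0, ConsumptionModel(4.0, 0.5))
        spec = DistributionSpec.lognormal(-1.0, 0.8)
        rng = np.random.default_rng(9)
        from dietrisk.exposure import simulate_concentration as sim_c

        conc = sim_c(spec, 0.6, 0.1, 10_000, rng)
        cons = group.consumption.sample(10_000, rng)
        r = np.corrcoef(conc, cons)[0, 1]
        assert abs(r) < 0.03

    def test_weight_equivariance(self):
        cons = np.array([10.0, 20.0, 30.0])
        conc = np.array([0.1, 0.2, 0.3])
        a = compute_edi(cons, conc, 50.0)
        b = compute_edi(cons, conc, 100.0)
        np.testing.assert_allclose(a, 2.0 * b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_edi([1.0, 2.0], [1.0], 50.0)

    def test_percentiles_monotone(self):
        expo = ExposureDistribution("X", "g", np.random.default_rng(0).gamma(2, 1, 5000))
        s = expo.summary()
        assert s["p50"] <= s["p75"] <= s["p95"] <= s["p99_9"]


class TestReaders:
    def test_demographics_csv_with_logparams(self, tmp_path):
        path = tmp_path / "demo.csv"
        path.write_text(
            "label,age_band,sex,weight_kg,log_mean,log_sd\n"
            "grp1,18-49,male,67.35,3.9,0.55\n"
        )
        groups = read_demographics(path)
        assert len(groups) == 1
        assert groups[0].weight_kg == 67.35
        assert groups[0].consumption.log_mean == 3.9

    def test_demographics_json_with_percentiles(self, tmp_path):
        import json

        path = tmp_path / "demo.json"
        path.write_text(
            json.dumps(
                [
                    {
                        "label": "grp1",
                        "age_band": "18-49",
                        "sex": "male",
                        "weight_kg": 67.35,
                        "percentiles": {"50": 51.3, "75": 88.8, "95": 140.6},
                    }
                ]
            )
        )
        groups = read_demographics(path)
        assert groups[0].consumption.quantile(0.5) == pytest.approx(51.3, rel=0.15)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,analyte,value\nS1,DEHP,0.2\n")
        with pytest.raises(ValidationError):
            read_concentration_csv(path)
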