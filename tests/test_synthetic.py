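"""Generator validation against closed-form OU and rainfall statistics."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from vegres.climate import interannual_variability, walsh_lawler_si
from vegres.resilience import estimate_ac1
from vegres.series import ResidualSeries
from vegres.synthetic import (
    ClassConfig,
    LandscapeConfig,
    OUParams,
    PerturbationTruth,
    PrecipGenParams,
    default_landscape_config,
    gen_landscape,
    gen_ou_residual,
    gen_precip_monthly,
    gen_vegetation_series,
    perturbation_component,
)


class TestOUGenerator:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            OUParams(lambda_true=0.5, sigma=0.1)  # unstable
        with pytest.raises(ValueError):
            OUParams(lambda_true=-1.0, sigma=0.1, dt=0.0)
        with pytest.raises(ValueError):
            OUParams(lambda_true=-1.0, sigma=0.1, n_steps=1)

    def test_noise_free_series_is_zero(self):
        r = gen_ou_residual(OUParams(-2.0, sigma=0.0, n_steps=100, seed=0))
        assert np.all(r.values == 0.0)

    def test_ensemble_variance_matches_stationary_closed_form(self):
        # Var = -sigma^2 / (2 lambda) = 0.0025 for lambda=-2, sigma=0.1
        params = [OUParams(-2.0, 0.1, n_steps=2000, seed=s) for s in range(60)]
        var = np.mean([np.var(gen_ou_residual(p).values) for p in params])
        assert var == pytest.approx(0.0025, rel=0.05)

    def test_sample_ac1_matches_exp_lambda_dt(self):
        r = gen_ou_residual(OUParams(-2.0, 0.1, n_steps=10_000, seed=1))
        assert estimate_ac1(r) == pytest.approx(np.exp(-2.0 / 24.0), abs=0.02)

    def test_seed_reproducibility(self):
        a = gen_ou_residual(OUParams(-2.0, 0.1, n_steps=500, seed=7))
        b = gen_ou_residual(OUParams(-2.0, 0.1, n_steps=500, seed=7))
        c = gen_ou_residual(OUParams(-2.0, 0.1, n_steps=500, seed=8))
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)


class TestVegetationComposer:
    def test_noise_free_series_is_seasonal_plus_trend(self):
        ou = OUParams(-2.0, 0.0, n_steps=240, seed=0)
        series, truth = gen_vegetation_series(ou, seasonal_amplitude=0.1, trend_slope=0.01)
        expected = truth["seasonal"] + truth["trend"]
        np.testing.assert_allclose(series.values, expected, atol=1e-12)

    def test_injected_drop_is_global_minimum(self):
        ou = OUParams(-2.0, 0.02, n_steps=720, seed=3)
        pert = [PerturbationTruth(time_index=360, amplitude=-0.5, recovery_rate_true=-2.0)]
        series, _ = gen_vegetation_series(
            ou, seasonal_amplitude=0.0, trend_slope=0.0, perturbations=pert, mean_level=0.0
        )
        assert abs(int(np.argmin(series.values)) - 360) <= 1

    def test_noise_free_recovery_is_log_linear(self):
        ou = OUParams(-2.0, 0.0, n_steps=480, seed=0)
        pert = [PerturbationTruth(time_index=120, amplitude=-0.3, recovery_rate_true=-2.0)]
        _, truth = gen_vegetation_series(ou, 0.0, 0.0, perturbations=pert, mean_level=0.0)
        comp = truth["perturbation_component"]
        t = np.arange(120, 480) / 24.0
        slope = np.polyfit(t - t[0], np.log(np.abs(comp[120:])), 1)[0]
        assert slope == pytest.approx(-2.0, abs=1e-9)

    def test_out_of_range_perturbation_rejected(self):
        with pytest.raises(ValueError):
            perturbation_component(100, 1 / 24, [PerturbationTruth(200, -0.1, -1.0)])


class TestPrecipGenerator:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PrecipGenParams(map_mm=500, month_weights=(0.5,) + (0.1,) * 11)

    def test_uniform_noise_free_months_equal(self):
        p = PrecipGenParams(map_mm=600, interannual_cv=0.0, n_years=3, month_noise_cv=0.0)
        series = gen_precip_monthly(p)
        np.testing.assert_allclose(series.values, 50.0)

    def test_single_month_concentration_gives_max_si(self):
        w = tuple(1.0 if i == 4 else 0.0 for i in range(12))
        p = PrecipGenParams(map_mm=400, month_weights=w, interannual_cv=0.0,
                            n_years=5, month_noise_cv=0.0)
        assert walsh_lawler_si(gen_precip_monthly(p)) == pytest.approx(11 / 6)

    def test_interannual_cv_recovered_at_large_n(self):
        p = PrecipGenParams(map_mm=800, interannual_cv=0.2, n_years=1000, seed=5,
                            month_noise_cv=0.0)
        assert interannual_variability(gen_precip_monthly(p)) == pytest.approx(0.20, abs=0.02)

    def test_scaling_map_scales_sums_but_not_si_or_cv(self):
        base = PrecipGenParams(map_mm=500, interannual_cv=0.25, n_years=40, seed=9)
        tripled = PrecipGenParams(map_mm=1500, interannual_cv=0.25, n_years=40, seed=9)
        a, b = gen_precip_monthly(base), gen_precip_monthly(tripled)
        np.testing.assert_allclose(b.annual_sums(), 3.0 * a.annual_sums(), rtol=1e-12)
        assert walsh_lawler_si(b) == pytest.approx(walsh_lawler_si(a), abs=1e-12)
        assert interannual_variability(b) == pytest.approx(
            interannual_variability(a), abs=1e-12
        )


class TestLandscape:
    def test_empty_landscape(self):
        land = gen_landscape(default_landscape_config(), seed=0, n_pixels=0)
        assert len(land.pixels) == 0
        assert len(land.truth) == 0
        assert land.veg.shape[0] == 0

    def test_empty_class_list_rejected(self):
        with pytest.raises(ValueError):
            gen_landscape(LandscapeConfig(classes=[]), seed=0)

    def test_truth_table_bookkeeping(self):
        cfg = LandscapeConfig(
            classes=[ClassConfig("savannas", n_pixels=60), ClassConfig("grasslands", n_pixels=60)],
            n_years=4,
        )
        land = gen_landscape(cfg, seed=1)
        assert len(land.truth) == 120
        assert land.truth["landcover"].value_counts().to_dict() == {
            "savannas": 60, "grasslands": 60,
        }
        assert land.veg.shape == (120, 96)
        assert land.labels.shape == (120, 4)
        # one class per pixel per year, constant by construction
        assert (land.labels.nunique(axis=1) == 1).all()

    def test_aridity_lambda_mapping_encodes_lower_resilience_when_drier(self):
        cfg = LandscapeConfig(classes=[ClassConfig("grasslands", n_pixels=300)], n_years=2)
        land = gen_landscape(cfg, seed=2)
        rho = spearmanr(land.truth["aridity_true"], land.truth["lambda_true"].abs()).statistic
        assert rho < -0.5  # drier -> |lambda| smaller -> lambda closer to zero

    def test_seed_determinism(self):
        cfg = LandscapeConfig(classes=[ClassConfig("savannas", n_pixels=25)], n_years=3)
        a, b = gen_landscape(cfg, seed=3), gen_landscape(cfg, seed=3)
        np.testing.assert_array_equal(a.veg, b.veg)
        np.testing.assert_array_equal(a.precip, b.precip)
        assert a.pixels.equals(b.pixels)
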