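"""Despiking, bi-weekly resampling, STL residuals, land-cover masking."""

import numpy as np
import pandas as pd
import pytest

from vegres.preprocess import (
    NATURAL_CLASSES,
    despike,
    landcover_mask,
    resample_biweekly,
    stl_residual,
)
from vegres.resilience import estimate_ac1
from vegres.series import VegetationSeries
from vegres.synthetic import OUParams, gen_ou_residual


def _series(values, dt=1 / 24):
    values = np.asarray(values, dtype=float)
    return VegetationSeries(values, np.arange(values.size) * dt)


class TestDespike:
    def test_clean_sinusoid_untouched(self):
        t = np.arange(240) / 24
        s = _series(0.5 + 0.2 * np.sin(2 * np.pi * t))
        out = despike(s)
        np.testing.assert_array_equal(out.values, s.values)
        assert out.despike_flags.sum() == 0

    def test_single_large_spike_replaced_and_flagged(self, rng):
        t = np.arange(240) / 24
        base = 0.5 + 0.1 * np.sin(2 * np.pi * t) + rng.normal(0, 0.01, 240)
        x = base.copy()
        x[100] -= 10 * 0.01 * 12  # far beyond local variability
        out = despike(_series(x))
        assert out.despike_flags.sum() == 1
        assert out.despike_flags[100]
        assert abs(out.values[100] - np.median(base[97:104])) < 0.05

    def test_unflagged_points_never_altered(self, rng):
        x = 0.4 + rng.normal(0, 0.02, 300)
        x[50] += 1.0
        s = _series(x)
        out = despike(s)
        keep = ~out.despike_flags
        np.testing.assert_array_equal(out.values[keep], s.values[keep])

    def test_sparse_spikes_mostly_caught(self, rng):
        # ~1% of points spiked at ~8 local MADs on a smooth seasonal base
        n = 2400
        t = np.arange(n) / 24
        base = 0.5 + 0.02 * np.sin(2 * np.pi * t) + rng.normal(0, 0.005, n)
        idx = rng.choice(n, size=24, replace=False)
        x = base.copy()
        x[idx] -= 0.12  # ~ 8 scaled MADs of the local variability
        out = despike(_series(x), window=7, k=4)
        caught = np.mean(out.despike_flags[idx])
        assert caught >= 0.95

    def test_window_validation(self):
        s = _series(np.zeros(10))
        with pytest.raises(ValueError):
            despike(s, window=4)
        with pytest.raises(ValueError):
            despike(s, window=11)


class TestResampleBiweekly:
    def test_daily_constant_stays_constant(self):
        t = np.arange(0, 2, 1 / 365.25)
        out = resample_biweekly(VegetationSeries(np.full(t.size, 0.5), t))
        assert np.nanmax(np.abs(out.values - 0.5)) == 0.0
        # 24 samples per year
        assert out.values.size == pytest.approx(48, abs=1)

    def test_bin_median(self):
        t = np.array([0.0, 0.01, 0.02, 0.05])
        out = resample_biweekly(VegetationSeries(np.array([0.1, 0.2, 0.9, 0.4]), t))
        assert out.values[0] == pytest.approx(0.2)  # median of first bin {0.1,0.2,0.9}
        assert out.values[1] == pytest.approx(0.4)

    def test_all_missing_bin_propagates(self):
        t = np.array([0.0, 0.01, 0.05, 0.06, 0.09])
        vals = np.array([0.1, 0.2, np.nan, np.nan, 0.3])
        out = resample_biweekly(VegetationSeries(vals, t))
        assert np.isnan(out.values[1])
        assert out.values[0] == pytest.approx(0.15)
        assert out.values[2] == pytest.approx(0.3)


class TestSTLResidual:
    def test_pure_sinusoid_residual_is_tiny(self):
        t = np.arange(720) / 24
        x = 0.5 + 0.2 * np.sin(2 * np.pi * t)
        res = stl_residual(VegetationSeries(x, t))
        assert np.sqrt(np.mean(res.values**2)) < 0.01 * 0.2

    def test_white_noise_variance_approximately_preserved(self):
        t = np.arange(720) / 24
        ratios = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            noise = rng.normal(0, 0.05, 720)
            x = 0.5 + 0.2 * np.sin(2 * np.pi * t) + 0.003 * t + noise
            res = stl_residual(VegetationSeries(x, t))
            ratios.append(np.var(res.values) / np.var(noise))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_ou_autocorrelation_distortion_is_bounded(self):
        # The ~2-year trend loess absorbs low-frequency OU power, so some
        # AC1 loss is inherent; it must stay bounded and sign-preserving.
        t = np.arange(720) / 24
        drops = []
        for seed in range(4):
            ou = gen_ou_residual(OUParams(24 * np.log(0.9), 0.1, n_steps=720, seed=seed + 1))
            x = 0.5 + 0.2 * np.sin(2 * np.pi * t) + ou.values
            res = stl_residual(VegetationSeries(x, t))
            drops.append(estimate_ac1(ou) - estimate_ac1(res))
        assert 0.0 < np.mean(drops) < 0.2

    def test_additivity_of_decomposition(self):
        t = np.arange(480) / 24
        rng = np.random.default_rng(3)
        x = 0.5 + 0.1 * np.sin(2 * np.pi * t) + rng.normal(0, 0.03, 480)
        res, comps = stl_residual(VegetationSeries(x, t), return_components=True)
        np.testing.assert_allclose(
            comps["seasonal"] + comps["trend"] + res.values, x, atol=1e-10
        )

    def test_idempotent_in_distribution(self):
        t = np.arange(720) / 24
        rng = np.random.default_rng(4)
        x = 0.5 + 0.2 * np.sin(2 * np.pi * t) + rng.normal(0, 0.05, 720)
        first = stl_residual(VegetationSeries(x, t))
        second = stl_residual(VegetationSeries(first.values + 0.5, t))
        assert np.var(second.values) == pytest.approx(np.var(first.values), rel=0.1)

    def test_short_series_rejected(self):
        t = np.arange(40) / 24
        with pytest.raises(ValueError):
            stl_residual(VegetationSeries(np.zeros(40), t))

    def test_too_many_missing_rejected(self):
        t = np.arange(720) / 24
        x = np.full(720, 0.5)
        x[: 200] = np.nan
        with pytest.raises(ValueError):
            stl_residual(VegetationSeries(x, t))

    def test_long_gaps_restored_to_missing(self):
        t = np.arange(720) / 24
        rng = np.random.default_rng(5)
        x = 0.5 + 0.2 * np.sin(2 * np.pi * t) + rng.normal(0, 0.02, 720)
        x[300:310] = np.nan  # 10-sample gap > max_gap=4
        x[500:502] = np.nan  # short gap, interpolated
        res = stl_residual(VegetationSeries(x, t))
        assert np.isnan(res.values[300:310]).all()
        assert np.isfinite(res.values[500:502]).all()


class TestLandcoverMask:
    def _labels(self, rows):
        return pd.DataFrame(rows, columns=[2001, 2002, 2003])

    def test_urban_ineligible_natural_eligible_change_ineligible(self):
        labels = self._labels(
            [
                ["urban", "urban", "urban"],
                ["savannas", "savannas", "savannas"],
                ["mixed_forest", "mixed_forest", "grasslands"],
            ]
        )
        mask = landcover_mask(labels)
        assert list(mask) == [False, True, False]

    def test_unknown_class_code_rejected(self):
        labels = self._labels([["savannas", "savannas", "not_a_class"]])
        with pytest.raises(ValueError, match="unknown"):
            landcover_mask(labels)

    def test_natural_set_is_configurable(self):
        labels = self._labels([["croplands"] * 3])
        assert not landcover_mask(labels).iloc[0]
        assert landcover_mask(labels, natural_classes=NATURAL_CLASSES | {"croplands"}).iloc[0]
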