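"""Binned medians, Kendall-Tau, Monte-Carlo surrogates, eligibility rules."""

import itertools

import numpy as np
import pandas as pd
import pytest

from vegres.relations import (
    RelateConfig,
    bin_medians,
    kendall_tau_binned,
    relate,
    results_to_frame,
    surrogate_taus,
)


def _brute_force_tau_b(x, y):
    """Pair-count Kendall tau-b oracle over all C(n,2) pairs."""
    conc = disc = tx = ty = 0
    for (xi, yi), (xj, yj) in itertools.combinations(zip(x, y), 2):
        if xi == xj and yi == yj:
            continue
        if xi == xj:
            tx += 1
        elif yi == yj:
            ty += 1
        elif (xi - xj) * (yi - yj) > 0:
            conc += 1
        else:
            disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


def _uniform_bins(k, per_bin, slope=1.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.concatenate([i + rng.uniform(0, 1, per_bin) for i in range(k)])
    y = slope * x + rng.normal(0, noise, x.size)
    edges = np.arange(k + 1.0)
    return x, y, edges


class TestBinMedians:
    def test_identity_relation_gives_increasing_medians(self):
        x, y, edges = _uniform_bins(12, 100)
        b = bin_medians(x, y, edges)
        assert b.reportable and b.n_eligible == 12
        med = b.medians[b.eligible]
        assert np.all(np.diff(med) > 0)

    def test_49_member_bin_ineligible(self):
        x, y, edges = _uniform_bins(12, 50)
        drop = np.flatnonzero((x >= 3) & (x < 4))[0]
        keep = np.ones(x.size, bool)
        keep[drop] = False
        b = bin_medians(x[keep], y[keep], edges)
        assert b.counts[3] == 49 and not b.eligible[3]
        assert b.n_eligible == 11

    def test_nine_eligible_bins_non_reportable(self):
        x, y, edges = _uniform_bins(9, 100)
        b = bin_medians(x, y, edges)
        assert b.n_eligible == 9 and not b.reportable

    def test_locality_adding_points_to_one_bin(self):
        x, y, edges = _uniform_bins(12, 60, seed=1)
        b0 = bin_medians(x, y, edges)
        x2 = np.concatenate([x, np.full(30, 5.5)])
        y2 = np.concatenate([y, np.full(30, 99.0)])
        b1 = bin_medians(x2, y2, edges)
        others = np.arange(12) != 5
        np.testing.assert_array_equal(b0.medians[others], b1.medians[others])

    def test_half_open_binning(self):
        b = bin_medians([0.0, 1.0, 2.0], [1.0, 2.0, 3.0], [0.0, 1.0, 2.0], min_count=1)
        # x == right edge of last bin is excluded; x == internal edge goes right
        assert b.counts.tolist() == [1, 1]


class TestKendallTau:
    def test_monotone_medians_give_unit_tau(self):
        x, y, edges = _uniform_bins(12, 60)
        tau, p = kendall_tau_binned(bin_medians(x, y, edges))
        assert tau == pytest.approx(1.0)
        assert p < 0.05
        tau_dec, _ = kendall_tau_binned(bin_medians(x, -y, edges))
        assert tau_dec == pytest.approx(-1.0)

    def test_matches_brute_force_pair_enumeration(self, rng):
        # known permutation with ties: tie-aware tau-b against the oracle
        med = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0])
        x = np.repeat(np.arange(10.0), 50) + 0.5
        y = np.repeat(med, 50)
        edges = np.arange(11.0)
        tau, _ = kendall_tau_binned(bin_medians(x, y, edges))
        assert tau == pytest.approx(_brute_force_tau_b(np.arange(10.0), med), abs=1e-12)

    def test_too_few_bins_raises(self):
        x, y, edges = _uniform_bins(5, 60)
        with pytest.raises(ValueError):
            kendall_tau_binned(bin_medians(x, y, edges))


class TestSurrogates:
    def test_singleton_bins_degenerate_to_median_line(self):
        x = np.arange(12) + 0.5
        y = 2.0 * x
        edges = np.arange(13.0)
        b = bin_medians(x, y, edges, min_count=1)
        s = surrogate_taus(x, y, b, n_iter=200, seed=0)
        assert np.all(s.taus == s.taus[0])
        assert s.taus[0] == pytest.approx(1.0)
        assert s.sign_fraction == 1.0

    def test_fixed_seed_reproducible(self):
        x, y, edges = _uniform_bins(12, 60, noise=2.0, seed=2)
        b = bin_medians(x, y, edges)
        a = surrogate_taus(x, y, b, n_iter=100, seed=42)
        c = surrogate_taus(x, y, b, n_iter=100, seed=42)
        np.testing.assert_array_equal(a.taus, c.taus)

    def test_sign_fraction_matches_empirical_frequency(self):
        x, y, edges = _uniform_bins(12, 60, noise=6.0, seed=3)
        b = bin_medians(x, y, edges)
        tau, _ = kendall_tau_binned(b)
        s = surrogate_taus(x, y, b, n_iter=500, seed=1)
        assert s.sign_fraction == pytest.approx(np.mean(s.taus * tau > 0))
        assert 0.0 <= s.sign_fraction <= 1.0

    def test_median_line_smoother_than_surrogates(self):
        # binned medians smooth bin-to-bin noise, so the median-line tau
        # magnitude dominates the surrogate median in nearly all runs
        wins = 0
        for seed in range(50):
            x, y, edges = _uniform_bins(12, 60, slope=0.3, noise=2.0, seed=seed)
            b = bin_medians(x, y, edges)
            tau, _ = kendall_tau_binned(b)
            s = surrogate_taus(x, y, b, n_iter=200, seed=seed)
            wins += abs(np.median(s.taus)) <= abs(tau)
        assert wins >= 48  # >= 95%


class TestRelate:
    def _table(self, n_per_class, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for cls, n in n_per_class.items():
            x = rng.uniform(0, 1, n)
            rows.append(pd.DataFrame({
                "landcover": cls,
                "aridity": x,
                "lambda_ac1": -4 + 3 * x + rng.normal(0, 0.3, n),
            }))
        return pd.concat(rows, ignore_index=True)

    def test_class_below_1000_points_omitted(self):
        t = self._table({"savannas": 999, "grasslands": 1500})
        res = relate(t, "aridity", "lambda_ac1")
        by = {r.landcover: r for r in res}
        assert by["savannas"].omitted_reason == "too_few_points"
        assert not by["savannas"].reportable
        assert by["grasslands"].reportable

    def test_monotone_truth_recovered_with_stable_sign(self):
        t = self._table({"grasslands": 2000}, seed=4)
        (r,) = relate(t, "aridity", "lambda_ac1")
        assert r.reportable and r.tau > 0 and r.p < 0.05
        sens_taus = [v[0] for v in r.sensitivity.values() if v[2]]
        assert len(sens_taus) == 3
        assert all(np.sign(s) == np.sign(r.tau) for s in sens_taus)

    def test_results_frame_roundtrip(self):
        t = self._table({"grasslands": 1200}, seed=5)
        frame = results_to_frame(relate(t, "aridity", "lambda_ac1"))
        assert frame.shape[0] == 1
        assert {"tau", "p", "sign_fraction", "reportable"} <= set(frame.columns)
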