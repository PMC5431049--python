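"""Coarse-series preparation: merge, screening, STL, Savitzky-Golay, seasons."""

from __future__ import annotations

import numpy as np
import numpy.testing as npt
import pytest
from statsmodels.tsa.seasonal import STL

from drycover.coarse_prep import (COARSE_SIGNALS, REL_CLOUD,
                                  REL_REMOVED, SRC_AQUA, SRC_TERRA,
                                  CoarseSeries, merge_terra_aqua,
                                  prepare_seasonal_features,
                                  savitzky_golay_smooth, screen_reliability,
                                  seasonal_statistics, stl_outlier_removal)


def _series(values, doys, flags=None, source=None, n_sig=1):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = np.repeat(values[:, None], n_sig, axis=1)
    return CoarseSeries.single_pixel(values, np.asarray(doys, float), flags, source)


def _px(series: CoarseSeries, signal: int = 0) -> np.ndarray:
    return series.values[:, signal, 0, 0]


class TestMerge:
    def test_union_sorted_by_doy(self):
        terra = _series([0.1], [12], source=[SRC_TERRA])
        aqua = _series([0.2], [20], source=[SRC_AQUA])
        merged = merge_terra_aqua(terra, aqua)
        npt.assert_array_equal(merged.doy[:, 0, 0], [12, 20])
        npt.assert_allclose(_px(merged), [0.1, 0.2])
        npt.assert_array_equal(merged.source[:, 0, 0], [SRC_TERRA, SRC_AQUA])

    def test_duplicate_doy_averaged(self):
        terra = _series([0.1, 0.5], [12, 20])
        aqua = _series([0.3], [20], source=[SRC_AQUA])
        merged = merge_terra_aqua(terra, aqua)
        valid = merged.valid_mask()[:, 0, 0]
        npt.assert_allclose(_px(merged)[valid], [0.1, 0.4])
        assert merged.n_valid()[0, 0] == 2

    def test_empty_aqua_is_identity(self):
        terra = _series([0.1, 0.2], [10, 30])
        aqua = CoarseSeries(np.empty((0, 1, 1, 1)), np.empty((0, 1, 1)),
                            np.empty((0, 1, 1), np.uint8),
                            np.empty((0, 1, 1), np.uint8),
                            terra.signal_names)
        merged = merge_terra_aqua(terra, aqua)
        npt.assert_allclose(_px(merged), [0.1, 0.2])

    def test_grid_mismatch_rejected(self):
        terra = _series([0.1], [10])
        aqua = CoarseSeries(np.zeros((1, 1, 2, 2)), np.zeros((1, 2, 2)),
                            np.zeros((1, 2, 2), np.uint8),
                            np.zeros((1, 2, 2), np.uint8),
                            terra.signal_names)
        with pytest.raises(ValueError):
            merge_terra_aqua(terra, aqua)

    def test_merge_and_screen_commute(self):
        rng = np.random.default_rng(4)
        flags_t = rng.integers(0, 5, 10).astype(np.uint8)
        flags_a = rng.integers(0, 5, 10).astype(np.uint8)
        vt, va = rng.random(10), rng.random(10)
        vt[flags_t >= 2] = np.nan
        va[flags_a >= 2] = np.nan
        terra = _series(vt, np.arange(1, 160, 16), flags=flags_t)
        aqua = _series(va, np.arange(9, 168, 16), flags=flags_a,
                       source=np.full(10, SRC_AQUA))
        a = screen_reliability(merge_terra_aqua(terra, aqua))
        b = merge_terra_aqua(screen_reliability(terra), screen_reliability(aqua))
        npt.assert_array_equal(a.valid_mask(), b.valid_mask())
        npt.assert_allclose(_px(a)[a.valid_mask()[:, 0, 0]],
                            _px(b)[b.valid_mask()[:, 0, 0]])


class TestScreen:
    def test_all_good_unchanged(self):
        s = _series([0.1, 0.2, 0.3], [10, 20, 30])
        out = screen_reliability(s)
        npt.assert_allclose(_px(out), [0.1, 0.2, 0.3])
        assert out.n_valid()[0, 0] == 3

    def test_cloud_flagged_removed(self):
        flags = np.zeros(46, dtype=np.uint8)
        flags[:5] = REL_CLOUD
        s = _series(np.linspace(0, 1, 46), np.arange(1, 369, 8), flags=flags)
        out = screen_reliability(s)
        assert out.n_valid()[0, 0] == 41
        assert (out.flags[:5, 0, 0] == REL_REMOVED).all()

    def test_all_flagged_empty(self):
        s = _series([0.1, 0.2], [10, 20], flags=[REL_CLOUD, REL_CLOUD])
        assert screen_reliability(s).n_valid()[0, 0] == 0


class TestSTL:
    def test_constant_series_untouched(self):
        s = _series(np.full(92, 0.4), np.arange(1, 737, 8))
        out = stl_outlier_removal(s, period=46)
        assert out.n_valid()[0, 0] == 92

    @staticmethod
    def _spiked_sinusoid():
        rng = np.random.default_rng(0)
        doys = np.arange(1.0, 1.0 + 368.0 * 4, 8.0)  # four cycles, 184 slots
        y = 0.4 + 0.3 * np.sin(2 * np.pi * doys / 368.0)
        y += rng.normal(0, 0.015, size=doys.size)
        y[40] += 0.5
        return y, doys

    def test_spike_removed_matching_decomposition_oracle(self):
        """A gross spike on a noisy sinusoid is removed, and the screening
        decision reproduces an independent per-series STL + MAD oracle.

        At finite cycle counts part of a spike leaks into the seasonal
        component, so its phase-mate slots in other cycles may also exceed
        the threshold; everything flagged must be the spike or a phase mate.
        """
        y, doys = self._spiked_sinusoid()
        out = stl_outlier_removal(_series(y, doys), period=46, k_sd=3.0,
                                  seasonal=15)
        removed = np.flatnonzero(~out.valid_mask()[:, 0, 0])
        resid = STL(y, period=46, seasonal=15).fit().resid
        mad = np.median(np.abs(resid - np.median(resid)))
        sd = max(1.4826 * mad, 1e-3)
        expected = np.flatnonzero(np.abs(resid) > 3.0 * sd)
        npt.assert_array_equal(removed, expected)
        assert 40 in removed
        assert all(min((p - 40) % 46, (40 - p) % 46) <= 1 for p in removed)
        assert len(removed) <= 6

    def test_screening_idempotent_on_clean_result(self):
        y, doys = self._spiked_sinusoid()
        once = stl_outlier_removal(_series(y, doys), period=46, k_sd=3.0,
                                   seasonal=15)
        twice = stl_outlier_removal(once, period=46, k_sd=3.0, seasonal=15)
        npt.assert_array_equal(once.valid_mask(), twice.valid_mask())

    def test_operator_matches_statsmodels_exactly(self):
        """The batched remainder operator equals per-series STL output."""
        from drycover.coarse_prep import _stl_remainder_operator

        rng = np.random.default_rng(12)
        y = rng.random((92, 4))
        R = _stl_remainder_operator(92, 46, 7)
        for j in range(4):
            direct = STL(y[:, j], period=46, seasonal=7).fit().resid
            npt.assert_allclose(R @ y[:, j], direct, atol=1e-8)

    def test_short_series_skipped_with_warning(self, caplog):
        s = _series([0.1, 0.2, 0.3], [1, 9, 17])
        with caplog.at_level("WARNING"):
            out = stl_outlier_removal(s, period=46)
        assert out.n_valid()[0, 0] == 3
        assert "too short" in caplog.text

    def test_single_year_spike_flagged_by_loess_fallback(self):
        rng = np.random.default_rng(3)
        doys = np.arange(1.0, 369.0, 8.0)  # 46 slots: < 2 periods
        y = 0.4 + 0.3 * np.sin(np.pi * (doys - 60) / 250.0)
        y += rng.normal(0, 0.01, size=doys.size)
        y[20] += 0.5
        out = stl_outlier_removal(_series(y, doys), period=46, k_sd=3.0)
        assert not out.valid_mask()[20, 0, 0]
        assert out.n_valid()[0, 0] >= 40


class TestSavitzkyGolay:
    def test_quadratic_reproduced_exactly(self):
        doys = np.arange(1.0, 369.0, 8.0)
        y = 0.2 + 0.001 * (doys / 8.0) + 0.0001 * (doys / 8.0) ** 2
        out = savitzky_golay_smooth(_series(y, doys), half_window=4, poly_order=2)
        npt.assert_allclose(_px(out), y, atol=1e-9)

    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_linear_reproduced_any_order(self, order):
        doys = np.arange(1.0, 369.0, 8.0)
        y = 0.1 + 0.002 * doys
        out = savitzky_golay_smooth(_series(y, doys), half_window=4,
                                    poly_order=order)
        npt.assert_allclose(_px(out), y, atol=1e-9)

    def test_interior_matches_least_squares_oracle(self):
        """Interior windows against a brute-force polynomial-fit oracle."""
        rng = np.random.default_rng(2)
        doys = np.arange(1.0, 369.0, 8.0)
        y = rng.random(doys.size)
        hw, order = 4, 2
        out = savitzky_golay_smooth(_series(y, doys), hw, order)
        smoothed = _px(out)
        for i in range(hw, doys.size - hw):
            t = np.arange(-hw, hw + 1, dtype=float)
            coef = np.polynomial.polynomial.polyfit(t, y[i - hw:i + hw + 1], order)
            npt.assert_allclose(smoothed[i], coef[0], atol=1e-9)

    def test_smoothing_is_linear(self):
        rng = np.random.default_rng(6)
        doys = np.arange(1.0, 369.0, 8.0)
        x, y = rng.random(doys.size), rng.random(doys.size)
        a, b = 0.3, 0.6
        sx = _px(savitzky_golay_smooth(_series(x, doys)))
        sy = _px(savitzky_golay_smooth(_series(y, doys)))
        sxy = _px(savitzky_golay_smooth(_series(a * x + b * y, doys)))
        npt.assert_allclose(sxy, a * sx + b * sy, atol=1e-10)

    def test_insufficient_observations_marked_missing(self):
        s = _series([0.1, 0.2], [1, 9])
        out = savitzky_golay_smooth(s, half_window=4, poly_order=2)
        assert np.isnan(_px(out)).all()

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            savitzky_golay_smooth(_series([0.1], [1]), half_window=1, poly_order=3)


class TestSeasonalStatistics:
    def _smoothed(self, values: np.ndarray) -> CoarseSeries:
        doys = 1.0 + 8.0 * np.arange(values.shape[0])
        return _series(values, doys, n_sig=6,
                       source=np.full(values.shape[0], 2))

    def test_constant_series(self):
        out = seasonal_statistics(self._smoothed(np.full(46, 0.5)))
        assert out.n_features == 90
        feats = dict(zip(out.names, out.features[:, 0, 0]))
        for sig in COARSE_SIGNALS:
            for season in ("spring", "summer", "autumn"):
                assert feats[f"{sig}_{season}_mean"] == pytest.approx(0.5)
                assert feats[f"{sig}_{season}_min"] == pytest.approx(0.5)
                assert feats[f"{sig}_{season}_max"] == pytest.approx(0.5)
                assert feats[f"{sig}_{season}_range"] == 0.0
                assert feats[f"{sig}_{season}_sd"] == 0.0

    def test_ramp_orders_means(self):
        doy = 1.0 + 8.0 * np.arange(46)
        out = seasonal_statistics(self._smoothed((doy - 1) / 364.0))
        feats = dict(zip(out.names, out.features[:, 0, 0]))
        assert feats["ndvi_summer_mean"] > feats["ndvi_spring_mean"] > 0
        assert feats["ndvi_autumn_mean"] > feats["ndvi_summer_mean"]

    def test_invariant_to_winter_values(self):
        rng = np.random.default_rng(9)
        base = rng.random(46)
        a = seasonal_statistics(self._smoothed(base))
        tampered = base.copy()
        doy = 1.0 + 8.0 * np.arange(46)
        winter = (doy < 60) | (doy > 334)
        assert winter.any()
        tampered[winter] = rng.random(winter.sum())
        b = seasonal_statistics(self._smoothed(tampered))
        npt.assert_array_equal(a.features, b.features)

    def test_range_nonnegative_and_order(self):
        rng = np.random.default_rng(10)
        out = seasonal_statistics(self._smoothed(rng.random(46)))
        feats = dict(zip(out.names, out.features[:, 0, 0]))
        for sig in COARSE_SIGNALS:
            for season in ("spring", "summer", "autumn"):
                assert feats[f"{sig}_{season}_range"] >= 0
                assert (feats[f"{sig}_{season}_min"]
                        <= feats[f"{sig}_{season}_mean"]
                        <= feats[f"{sig}_{season}_max"])


def test_pipeline_deterministic(tiny_truth):
    from drycover.scene import simulate_coarse_series

    terra, aqua = simulate_coarse_series(tiny_truth)
    a = prepare_seasonal_features(terra, aqua)
    b = prepare_seasonal_features(terra, aqua)
    npt.assert_array_equal(a.features, b.features)
    assert a.names == b.names
    assert a.n_features == 90
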