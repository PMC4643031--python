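"""Vegetation indices, seasonal fitting, phenology, statistics, terrain."""

from __future__ import annotations

import numpy as np
import pytest

from lulcfuse.features import (
    GROWING_SEASON_WINDOW,
    FLAT_ASPECT_SENTINEL,
    asymmetric_gaussian,
    assemble_features,
    compute_evi,
    compute_ndvi,
    extract_phenology,
    feature_names_for_combo,
    fit_upper_envelope,
    qa_to_weight,
    seasonal_statistics,
    terrain_derivatives,
)
from lulcfuse.synthetic import COMPOSITE_DOYS

DATES = np.asarray(COMPOSITE_DOYS, dtype=float)


class TestIndices:
    @pytest.mark.parametrize(
        "red,nir,expected",
        [(0.3, 0.3, 0.0), (0.1, 0.5, 0.6666667), (0.2, 0.6, 0.5)],
    )
    def test_ndvi_values(self, red, nir, expected):
        assert compute_ndvi(red, nir) == pytest.approx(expected, abs=1e-6)

    def test_ndvi_zero_denominator_is_nodata(self):
        assert np.isnan(compute_ndvi(0.0, 0.0))

    def test_evi_zero_when_nir_equals_red(self):
        assert compute_evi(0.05, 0.3, 0.3) == pytest.approx(0.0)

    def test_evi_hand_computed_value(self):
        # 2.5 * 0.3 / (0.4 + 0.6 - 0.375 + 1)
        assert compute_evi(0.05, 0.1, 0.4) == pytest.approx(0.75 / 1.625, abs=1e-6)

    def test_evi_degenerate_denominator_is_nodata(self):
        # nir + 6*red - 7.5*blue + 1 == 0
        assert np.isnan(compute_evi(0.2, 0.05, 0.2))


class TestQaWeights:
    @pytest.mark.parametrize("qa,w", [(0, 1.0), (1, 0.5), (2, 0.5), (3, 0.1)])
    def test_mapping(self, qa, w):
        assert qa_to_weight(qa) == w

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError, match="0..3"):
            qa_to_weight(np.array([0, 5]))


class TestUpperEnvelope:
    def test_noiseless_curve_recovered(self):
        params = np.array([0.2, 0.5, 200.0, 30.0, 25.0])
        clean = asymmetric_gaussian(DATES, params[None])[0]
        smoothed = fit_upper_envelope(clean, np.ones_like(clean), DATES)
        rms = np.sqrt(np.mean((smoothed - clean) ** 2))
        assert rms < 1e-3

    def test_cloud_dropout_is_repaired(self):
        params = np.array([0.2, 0.5, 200.0, 30.0, 25.0])
        clean = asymmetric_gaussian(DATES, params[None])[0]
        contaminated = clean.copy()
        weights = np.ones_like(clean)
        i = int(np.argmax(clean))  # worst case: drop the peak composite
        contaminated[i] = 0.0
        weights[i] = qa_to_weight(3)
        smoothed = fit_upper_envelope(contaminated, weights, DATES)
        assert abs(smoothed[i] - clean[i]) < 0.05

    def test_constant_series_stays_constant(self):
        const = np.full(DATES.size, 0.31)
        smoothed = fit_upper_envelope(const, np.ones_like(const), DATES)
        np.testing.assert_allclose(smoothed, const, atol=1e-6)

    def test_too_few_valid_points_yields_nodata(self):
        y = np.full(DATES.size, np.nan)
        y[:3] = 0.5
        smoothed = fit_upper_envelope(y, np.ones_like(y), DATES)
        assert np.isnan(smoothed).all()

    def test_all_minimum_weights_warns_but_fits(self):
        params = np.array([0.2, 0.5, 200.0, 30.0, 25.0])
        clean = asymmetric_gaussian(DATES, params[None])[0]
        with pytest.warns(UserWarning, match="minimum"):
            smoothed = fit_upper_envelope(clean, np.full_like(clean, 0.1), DATES)
        assert np.isfinite(smoothed).all()


class TestPhenology:
    def test_symmetric_gaussian_crossings(self):
        daily = np.arange(50.0, 351.0)
        curve = 0.2 + 0.5 * np.exp(-0.5 * ((daily - 200.0) / 30.0) ** 2)
        m = extract_phenology(curve, daily, season_fraction=0.2)
        assert m.mid_doy[0] == pytest.approx(200.0, abs=1.0)
        # analytic 20%-amplitude crossing: 200 ± 30*sqrt(2 ln 5)
        offset = 30.0 * np.sqrt(2.0 * np.log(5.0))
        assert m.start_doy[0] == pytest.approx(200.0 - offset, abs=1.5)
        assert m.end_doy[0] == pytest.approx(200.0 + offset, abs=1.5)
        assert abs((200.0 - m.start_doy[0]) - (m.end_doy[0] - 200.0)) <= 2.0
        assert m.amplitude[0] == pytest.approx(0.5, rel=0.02)

    def test_flat_series_has_no_season(self):
        m = extract_phenology(np.full(DATES.size, 0.3), DATES)
        assert bool(m.no_season[0])
        assert np.isnan(m.amplitude[0])

    def test_triangle_integral_matches_area(self):
        # base 0.1 everywhere, one triangular season of height 0.4
        daily = np.arange(1.0, 366.0)
        curve = np.full(daily.size, 0.1)
        rise = (daily >= 150) & (daily <= 200)
        fall = (daily > 200) & (daily <= 250)
        curve[rise] += 0.4 * (daily[rise] - 150) / 50.0
        curve[fall] += 0.4 * (250 - daily[fall]) / 50.0
        m = extract_phenology(curve, daily, season_fraction=0.0)
        # area above base of a triangle: 0.5 * 100 days * 0.4
        assert m.integral_small[0] == pytest.approx(20.0, rel=0.02)

    def test_metric_internal_consistency(self):
        params = np.array([[0.15, 0.45, 190.0, 28.0, 35.0]])
        curve = asymmetric_gaussian(DATES, params)
        m = extract_phenology(curve, DATES)
        assert m.start_doy[0] < m.mid_doy[0] < m.end_doy[0]
        assert m.amplitude[0] == pytest.approx(m.peak[0] - m.base[0], abs=1e-9)
        assert m.season_length[0] == pytest.approx(m.end_doy[0] - m.start_doy[0])
        assert m.integral_small[0] <= m.integral_large[0]


class TestSeasonalStats:
    def test_constant_band(self):
        vals = np.full((1, DATES.size), 0.4)
        stats = seasonal_statistics(vals, DATES)
        mean, sd, mn, mx, rng_ = stats[0]
        assert mean == pytest.approx(0.4) and mn == mx == 0.4
        assert sd == pytest.approx(0.0) and rng_ == 0.0

    def test_simple_values(self):
        dates = np.array([100.0, 150.0, 200.0])
        stats = seasonal_statistics(np.array([[0.2, 0.4, 0.6]]), dates)
        assert stats[0, 0] == pytest.approx(0.4)  # mean
        assert stats[0, 4] == pytest.approx(0.4)  # range

    def test_window_excluding_all_dates_is_nodata(self):
        stats = seasonal_statistics(
            np.ones((1, DATES.size)), DATES, window=(400.0, 500.0)
        )
        assert np.isnan(stats).all()

    def test_matches_bruteforce_on_random_cubes(self, rng):
        vals = rng.random((40, DATES.size))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        lo, hi = GROWING_SEASON_WINDOW
        stats = seasonal_statistics(vals, DATES)
        keep = (DATES >= lo) & (DATES <= hi)
        for i in range(vals.shape[0]):
            v = vals[i, keep]
            v = v[np.isfinite(v)]
            expect = [
                v.mean(),
                v.std(ddof=1) if v.size > 1 else 0.0,
                v.min(),
                v.max(),
                v.max() - v.min(),
            ]
            np.testing.assert_allclose(stats[i], expect, atol=1e-12)


class TestTerrain:
    def test_flat_plane(self):
        slope, aspect = terrain_derivatives(np.full((8, 8), 500.0), 30.0)
        assert np.all(slope == 0)
        assert np.all(aspect == FLAT_ASPECT_SENTINEL)

    def test_south_dipping_45_degrees(self):
        # z increases northward 1 m per metre of grid
        rows = np.arange(10)[::-1].astype(float)
        dem = np.repeat(rows[:, None], 10, axis=1) * 30.0
        slope, aspect = terrain_derivatives(dem, 30.0)
        inner = (slice(1, -1), slice(1, -1))
        np.testing.assert_allclose(slope[inner], 45.0, atol=1e-6)
        np.testing.assert_allclose(aspect[inner], 180.0, atol=1e-6)

    def test_east_facing_ramp(self):
        cols = np.arange(10)[::-1].astype(float)
        dem = np.repeat(cols[None, :], 10, axis=0) * 10.0
        _, aspect = terrain_derivatives(dem, 30.0)
        inner = (slice(1, -1), slice(1, -1))
        np.testing.assert_allclose(aspect[inner], 90.0, atol=1e-6)

    def test_all_nodata_rejected(self):
        with pytest.raises(ValueError, match="no valid"):
            terrain_derivatives(np.full((4, 4), np.nan))


class TestAssembly:
    @pytest.mark.parametrize("combo,n", [("C1", 33), ("C2", 14), ("C3", 44)])
    def test_feature_counts(self, combo, n, small_scene):
        _, cube, dem, _ = small_scene
        rows = np.array([10, 20, 30])
        cols = np.array([10, 20, 30])
        table = assemble_features(cube, dem, combo, points=(rows, cols))
        assert table.n_features == n
        assert len(set(table.feature_names)) == n
        assert np.isfinite(table.values).all()

    def test_c3_is_union_without_duplicate_terrain(self):
        c1 = set(feature_names_for_combo("C1"))
        c2 = set(feature_names_for_combo("C2"))
        c3 = feature_names_for_combo("C3")
        assert set(c3) == c1 | c2
        assert len(c3) == len(set(c3)) == 44

    def test_unknown_combo_rejected(self, small_scene):
        _, cube, dem, _ = small_scene
        with pytest.raises(ValueError, match="C9"):
            assemble_features(cube, dem, "C9")

    def test_no_season_pixels_imputed_not_dropped(self, small_scene, scheme):
        _, cube, dem, truth = small_scene
        rr, cc = np.nonzero(truth.labels == scheme.code_of("WATR"))
        table = assemble_features(cube, dem, "C2", points=(rr[:20], cc[:20]))
        assert table.n_samples == 20
        assert np.isfinite(table.values).all()
        amp = table.values[:, table.feature_names.index("pheno_amplitude")]
        assert np.all(amp <= 0.06)  # water has essentially no season
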