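"""Design-matrix blocks: orthogonal trend, day-type harmonics, indicators."""

import numpy as np
import pytest

from diurnality.basis import (WIDTH_PRESETS, DesignMatrices, RankError,
                              TrendBasis, build_harmonic_basis,
                              build_nuisance_basis, build_trend_basis,
                              harmonic_column_names)
from diurnality.simulate import SyntheticSpec, simulate_series


class TestTrendBasis:
    def test_orthonormal_on_observed_rows(self):
        d = np.arange(10.0)
        Q = build_trend_basis(d)
        full = np.column_stack([np.ones(10) / np.sqrt(10), Q])
        np.testing.assert_allclose(full.T @ full, np.eye(4), atol=1e-10)

    def test_first_column_is_increasing_affine_in_days(self):
        d = np.linspace(0, 365, 200)
        Q = build_trend_basis(d)
        slopes = np.diff(Q[:, 0]) / np.diff(d)
        assert np.all(slopes > 0)
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-9)

    def test_exactly_reproduces_a_cubic(self):
        d = np.linspace(0, 20, 50)
        y = 2 * d**3 - d
        Q = build_trend_basis(d)
        X = np.column_stack([np.ones_like(d), Q])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(X @ beta, y, atol=1e-8)

    def test_transform_agrees_with_fit_rows(self):
        d = np.linspace(0, 50, 64)
        tb, Q = TrendBasis.fit(d)
        np.testing.assert_allclose(tb.transform(d), Q, atol=1e-12)

    def test_too_few_distinct_points_is_rank_error(self):
        with pytest.raises(RankError):
            build_trend_basis(np.array([1.0, 1.0, 2.0, 2.0, 3.0]))


class TestHarmonicBasis:
    def test_midnight_row_cos_one_sin_zero(self):
        H = build_harmonic_basis(np.array([0]), np.array([False]))
        names = harmonic_column_names()
        row = dict(zip(names, H[0]))
        for n in range(1, 5):
            assert row[f"weekday_cos{n}"] == pytest.approx(1.0)
            assert row[f"weekday_sin{n}"] == pytest.approx(0.0, abs=1e-12)

    def test_quarter_period_values_at_six(self):
        H = build_harmonic_basis(np.array([6]), np.array([False]))
        row = dict(zip(harmonic_column_names(), H[0]))
        assert row["weekday_sin1"] == pytest.approx(1.0)
        assert row["weekday_cos1"] == pytest.approx(0.0, abs=1e-12)
        assert row["weekday_sin2"] == pytest.approx(0.0, abs=1e-12)
        assert row["weekday_cos2"] == pytest.approx(-1.0)

    def test_weekday_row_zero_in_weekend_columns(self):
        H = build_harmonic_basis(np.array([9]), np.array([False]))
        row = dict(zip(harmonic_column_names(), H[0]))
        weekend_cols = [v for k, v in row.items() if k.startswith("weekend")]
        assert weekend_cols == [0.0] * 9  # 8 harmonics + level

    def test_columns_bounded_by_one(self):
        rng = np.random.default_rng(0)
        hours = rng.integers(0, 24, 500)
        weekend = rng.random(500) < 0.3
        H = build_harmonic_basis(hours, weekend)
        assert np.all(np.abs(H) <= 1.0 + 1e-12)

    def test_complete_weekday_day_sums_to_zero(self):
        H = build_harmonic_basis(np.arange(24), np.zeros(24, dtype=bool))
        sums = H[:, :16].sum(axis=0)
        np.testing.assert_allclose(sums, 0.0, atol=1e-10)

    def test_hour_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_harmonic_basis(np.array([24]), np.array([False]))


class TestNuisanceBasis:
    def test_two_whole_weeks(self):
        mat, meta = build_nuisance_basis(336, {168})
        assert mat.shape == (336, 2)
        np.testing.assert_array_equal(np.asarray(mat.sum(axis=0)).ravel(),
                                      [168, 168])
        assert meta == [(168, 0), (168, 1)]

    def test_truncated_final_window_kept(self):
        mat, meta = build_nuisance_basis(20, {8})
        assert meta == [(8, 0), (8, 1), (8, 2)]
        np.testing.assert_array_equal(np.asarray(mat.sum(axis=0)).ravel(),
                                      [8, 8, 4])

    def test_row_membership(self):
        mat, meta = build_nuisance_basis(20, {8})
        row = mat[10].toarray().ravel()
        assert row[meta.index((8, 1))] == 1.0
        assert row.sum() == 1.0

    @pytest.mark.parametrize("preset", sorted(WIDTH_PRESETS))
    def test_each_width_partitions_the_axis(self, preset):
        widths = WIDTH_PRESETS[preset]
        n = 400
        mat, meta = build_nuisance_basis(n, widths)
        arr = mat.toarray()
        for k in widths:
            cols = [j for j, (kk, _) in enumerate(meta) if kk == k]
            np.testing.assert_array_equal(arr[:, cols].sum(axis=1), 1.0)

    def test_invalid_widths_rejected(self):
        with pytest.raises(ValueError):
            build_nuisance_basis(100, {0})
        with pytest.raises(ValueError):
            build_nuisance_basis(100, {168})  # wider than the series


class TestDesignMatrices:
    def test_from_annotations_shapes_and_names(self):
        series, _ = simulate_series(SyntheticSpec(n_hours=400, noise_sd=0.0))
        design = DesignMatrices.from_annotations(series.frame,
                                                 widths=(8, 16, 168))
        assert design.trend.shape == (400, 3)
        assert design.harmonic.shape == (400, 17)
        assert design.nuisance.shape[0] == 400
        assert len(design.nuisance_meta) == design.nuisance.shape[1]
        assert design.harmonic_names[-1] == "weekend_level"

    def test_unknown_preset_rejected(self):
        series, _ = simulate_series(SyntheticSpec(n_hours=400, noise_sd=0.0))
        with pytest.raises(ValueError, match="preset"):
            DesignMatrices.from_annotations(series.frame, widths="bogus")
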