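"""Selection, OLS recovery, filtering, and the estimator facade."""

import itertools

import numpy as np
import pytest
from sklearn.base import clone

from diurnality.basis import DesignMatrices
from diurnality.model import (DiurnalHarmonicRegression, fit_ols, fit_series,
                              filter_series, select_nuisance)
from diurnality.simulate import (Harmonic, Surge, SyntheticSpec,
                                 phase_for_peak, simulate_series)
import diurnality.summaries as S

N_SMALL = 2000  # about 12 weeks of hourly data


def small_spec(**kwargs):
    defaults = dict(n_hours=N_SMALL, baseline=50.0, trend_coeffs=(2.0, -1.0, 0.5),
                    weekday_harmonics=(Harmonic(1, 10.0, phase_for_peak(1, 5.0)),
                                       Harmonic(2, 3.0, phase_for_peak(2, 2.0))),
                    weekend_harmonics=(Harmonic(1, 6.0, phase_for_peak(1, 7.0)),),
                    noise_sd=0.0, seed=0)
    defaults.update(kwargs)
    return SyntheticSpec(**defaults)


@pytest.fixture(scope="module")
def small_design():
    series, _ = simulate_series(small_spec())
    return DesignMatrices.from_annotations(series.frame)


class TestSelectNuisance:
    def test_clean_harmonic_signal_selects_nothing(self, small_design):
        spurious = 0
        for seed in range(5):
            series, _ = simulate_series(small_spec(seed=seed))
            spurious += len(select_nuisance(series.rsv, small_design))
        assert spurious <= 1

    def test_surge_matching_one_indicator_is_selected(self, small_design):
        series, _ = simulate_series(
            small_spec(noise_sd=5.0, outliers=(Surge(800, 8, 60.0),), seed=3))
        selected = select_nuisance(series.rsv, small_design)
        assert (8, 100) in selected

    def test_two_disjoint_surges_both_covered(self, small_design):
        surges = (Surge(480, 8, 60.0), Surge(1200, 16, 50.0))
        series, _ = simulate_series(
            small_spec(noise_sd=5.0, outliers=surges, seed=5))
        selected = select_nuisance(series.rsv, small_design)
        for s in surges:
            hours = set(range(s.start_hour, s.start_hour + s.duration_hours))
            covered = set()
            for k, m in selected:
                covered.update(range(k * m, k * (m + 1)))
            assert hours <= covered, (selected, s)

    def test_matches_best_subset_when_support_is_strong(self):
        # small instance: 240 hours, width-8 ladder -> 30 candidate columns;
        # the LASSO-selected support and its OLS fit should coincide with an
        # exhaustive best-subset search of the same size
        series, _ = simulate_series(small_spec(
            n_hours=240, noise_sd=1.0, trend_coeffs=(0, 0, 0),
            outliers=(Surge(80, 8, 50.0),), seed=11))
        design = DesignMatrices.from_annotations(series.frame, widths=(8,))
        y = series.rsv
        selected = select_nuisance(y, design, cv_folds=10)
        assert len(selected) >= 1
        U = design.unpenalized
        Nd = design.nuisance.toarray()

        def rss_of(cols):
            X = np.column_stack([U, Nd[:, list(cols)]])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(((y - X @ beta) ** 2).sum())

        best = min(itertools.combinations(range(Nd.shape[1]), len(selected)),
                   key=rss_of)
        best_meta = sorted(design.nuisance_meta[j] for j in best)
        assert best_meta == sorted(selected)
        model = fit_ols(y, design, selected)
        X_best = np.column_stack([U, Nd[:, list(best)]])
        beta_best, *_ = np.linalg.lstsq(X_best, y, rcond=None)
        np.testing.assert_allclose(
            np.r_[model.intercept, model.trend_coeffs, model.harmonic_coeffs,
                  model.weekend_level],
            beta_best[:21], rtol=1e-8, atol=1e-10)


class TestFitOls:
    def test_noiseless_recovery_to_machine_precision(self, small_design):
        series, truth = simulate_series(small_spec())
        model = fit_ols(series.rsv, small_design, [])
        for (dt, n, fn), v in truth.harmonic_coefs.items():
            assert model.harmonic_coef(dt, n, fn) == pytest.approx(v, rel=1e-8)

    def test_constant_series_gives_intercept_only(self, small_design):
        model = fit_ols(np.full(N_SMALL, 50.0), small_design, [])
        assert model.intercept == pytest.approx(50.0, abs=1e-9)
        np.testing.assert_allclose(model.trend_coeffs, 0.0, atol=1e-9)
        np.testing.assert_allclose(model.harmonic_coeffs, 0.0, atol=1e-9)
        assert model.weekend_level == pytest.approx(0.0, abs=1e-9)

    def test_location_shift_moves_intercept_only(self, small_design):
        series, _ = simulate_series(small_spec(noise_sd=3.0, seed=2))
        m0 = fit_ols(series.rsv, small_design, [])
        m1 = fit_ols(series.rsv + 10.0, small_design, [])
        assert m1.intercept - m0.intercept == pytest.approx(10.0, abs=1e-8)
        np.testing.assert_allclose(m1.harmonic_coeffs, m0.harmonic_coeffs,
                                   atol=1e-9)
        np.testing.assert_allclose(m1.trend_coeffs, m0.trend_coeffs, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, small_design):
        series, _ = simulate_series(
            small_spec(noise_sd=5.0, outliers=(Surge(800, 8, 60.0),), seed=3))
        selected = select_nuisance(series.rsv, small_design)
        model = fit_ols(series.rsv, small_design, selected)
        cols = [small_design.nuisance_meta.index(km) for km in selected]
        X = np.column_stack([small_design.unpenalized,
                             small_design.nuisance[:, cols].toarray()])
        Xs = X / np.linalg.norm(X, axis=0, keepdims=True)
        assert np.abs(Xs.T @ model.residuals).max() <= 1e-6

    def test_unknown_selected_column_rejected(self, small_design):
        with pytest.raises(ValueError, match="not in the design"):
            fit_ols(np.full(N_SMALL, 50.0), small_design, [(8, 10**6)])


class TestFilterSeries:
    def test_no_selection_is_identity(self, small_design):
        series, _ = simulate_series(small_spec(noise_sd=3.0, seed=4))
        model = fit_ols(series.rsv, small_design, [])
        np.testing.assert_array_equal(filter_series(model), series.rsv)

    def test_surge_removed_to_within_noise(self, small_design):
        spec = small_spec(noise_sd=5.0, outliers=(Surge(800, 8, 60.0),), seed=6)
        series, truth = simulate_series(spec)
        selected = select_nuisance(series.rsv, small_design)
        model = fit_ols(series.rsv, small_design, selected)
        clean = truth.mean_curve  # surge-free noiseless mean
        window = slice(800, 808)
        err = np.abs(filter_series(model)[window] - clean[window])
        assert err.max() < 4 * spec.noise_sd

    def test_refiltering_noiseless_filtered_series_selects_nothing(self, small_design):
        series, _ = simulate_series(small_spec(outliers=(Surge(800, 8, 60.0),)))
        selected = select_nuisance(series.rsv, small_design)
        model = fit_ols(series.rsv, small_design, selected)
        again = select_nuisance(filter_series(model), small_design)
        assert again == []


class TestEstimatorFacade:
    def test_fit_exposes_sklearn_style_attributes(self):
        series, _ = simulate_series(small_spec(noise_sd=3.0, seed=8))
        est = DiurnalHarmonicRegression(select=False)
        assert clone(est).get_params()["select"] is False
        est.fit(series)
        assert est.intercept_ == pytest.approx(est.model_.intercept)
        assert est.harmonic_coeffs_.shape == (16,)
        assert len(est.filtered_series_) == len(series)

    def test_predict_matches_fitted_values(self):
        series, _ = simulate_series(
            small_spec(noise_sd=3.0, outliers=(Surge(800, 8, 60.0),), seed=9))
        est = DiurnalHarmonicRegression().fit(series)
        pred = est.predict(series, include_nuisance=True)
        np.testing.assert_allclose(pred, est.model_.fitted, atol=1e-8)

    def test_fit_series_convenience_equals_estimator(self):
        series, _ = simulate_series(small_spec(noise_sd=3.0, seed=8))
        m = fit_series(series, select=False)
        est = DiurnalHarmonicRegression(select=False).fit(series)
        np.testing.assert_allclose(m.harmonic_coeffs, est.harmonic_coeffs_)

    def test_amplitude_error_shrinks_after_filtering(self, small_design):
        # surge-contaminated fits: filtering should move the day-type AMRs
        # toward truth in most replications
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            spec = small_spec(noise_sd=5.0,
                              outliers=(Surge(640, 8, 80.0),), seed=100 + seed)
            series, truth = simulate_series(spec)
            sel = select_nuisance(series.rsv, small_design)
            with_filter = fit_ols(series.rsv, small_design, sel)
            without = fit_ols(series.rsv, small_design, [])

            def amr_err(model):
                return sum(
                    abs(S.amplitude_mean_ratio(S.diurnal_curve(model, dt))
                        - truth.amr[dt]) for dt in ("weekday", "weekend"))

            wins += amr_err(with_filter) < amr_err(without)
        assert wins >= 0.7 * n_seeds
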