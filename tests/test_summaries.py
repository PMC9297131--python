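"""Circular summaries: closed forms, oracle agreement, invariances."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from diurnality.simulate import OMEGA
from diurnality.summaries import (DiurnalCurve, UndefinedStatisticError,
                                  amplitude_mean_ratio, amr_contrast_from_curves,
                                  circular_difference, circular_median_time,
                                  format_clock, median_diff_band, minute_grid,
                                  polar_normalize)


def cosine_curve(mean, amp, peak_hour, n=1, daytype="weekday", extra=None):
    t = minute_grid()
    v = mean + amp * np.cos(n * OMEGA * (t - peak_hour))
    if extra is not None:
        v = v + extra(t)
    return DiurnalCurve(daytype=daytype, grid=t, values=v)


def brute_force_circular_median(values, grid):
    """Independent exhaustive minimizer of weighted mean arc distance."""
    w = values - values.min()
    best, best_score = None, np.inf
    for j, tj in enumerate(grid):
        d = np.abs(grid - tj)
        d = np.minimum(d, 24.0 - d)
        score = float(w @ d)
        if score < best_score - 1e-12:
            best, best_score = tj, score
    return best


class TestAmplitudeMeanRatio:
    def test_closed_form_single_harmonic(self):
        assert amplitude_mean_ratio(cosine_curve(10, 3, 0)) == pytest.approx(
            0.6, abs=1e-9)

    def test_constant_curve_is_zero(self):
        curve = DiurnalCurve("weekday", minute_grid(), np.full(1440, 7.0))
        assert amplitude_mean_ratio(curve) == 0.0

    def test_nonpositive_mean_rejected(self):
        curve = DiurnalCurve("weekday", minute_grid(), np.full(1440, -1.0))
        with pytest.raises(UndefinedStatisticError):
            amplitude_mean_ratio(curve)

    def test_two_harmonic_ratio_stable_under_grid_refinement(self):
        def extra(t):
            return 1.0 * np.cos(2 * OMEGA * t)
        coarse = cosine_curve(10, 3, 0, extra=extra)
        t_fine = np.arange(0, 24, 0.5 / 60)
        fine = DiurnalCurve("weekday", t_fine,
                            10 + 3 * np.cos(OMEGA * t_fine)
                            + 1.0 * np.cos(2 * OMEGA * t_fine))
        assert amplitude_mean_ratio(coarse) == pytest.approx(
            amplitude_mean_ratio(fine), abs=1e-6)

    @given(st.floats(min_value=0.1, max_value=20),
           st.floats(min_value=0, max_value=24))
    def test_shift_and_scale_invariance(self, c, shift):
        base = cosine_curve(10, 3, 5)
        shifted = cosine_curve(10, 3, (5 + shift) % 24)
        scaled = DiurnalCurve("weekday", base.grid, c * base.values)
        r = amplitude_mean_ratio(base)
        # off-grid peaks move the sampled extrema by up to half a grid step
        assert amplitude_mean_ratio(shifted) == pytest.approx(r, abs=2e-5)
        assert amplitude_mean_ratio(scaled) == pytest.approx(r, abs=1e-9)


class TestCircularMedian:
    def test_unimodal_peak_recovered(self):
        assert circular_median_time(cosine_curve(10, 3, 5)) == pytest.approx(
            5.0, abs=1 / 60)

    @pytest.mark.parametrize("shift", [1.0, 6.5, 13.0, 23.0])
    def test_shift_equivariance(self, shift):
        m0 = circular_median_time(cosine_curve(10, 3, 4))
        m1 = circular_median_time(cosine_curve(10, 3, (4 + shift) % 24))
        assert abs(circular_difference(m0 + shift, m1)) <= 1 / 60 + 1e-9

    def test_single_harmonic_matches_analytic_peak(self):
        for peak in np.linspace(0, 23.9, 12):
            med = circular_median_time(cosine_curve(50, 10, peak))
            assert abs(circular_difference(med, peak)) <= 1 / 60 + 1e-9

    def test_bimodal_curve_matches_exhaustive_search(self):
        t = minute_grid()
        values = (10 + 3 * np.cos(OMEGA * (t - 4))
                  + 1 * np.cos(OMEGA * (t - 16)) + 2 * np.cos(2 * OMEGA * t))
        curve = DiurnalCurve("weekday", t, values)
        assert circular_median_time(curve) == pytest.approx(
            brute_force_circular_median(values, t), abs=1e-9)

    def test_constant_curve_undefined(self):
        curve = DiurnalCurve("weekday", minute_grid(), np.full(1440, 3.0))
        with pytest.raises(UndefinedStatisticError):
            circular_median_time(curve)


class TestAmrContrast:
    def test_identical_curves_zero(self):
        a = cosine_curve(10, 3, 5)
        b = cosine_curve(10, 3, 5, daytype="weekend")
        assert amr_contrast_from_curves(a, b) == 0.0

    def test_closed_form(self):
        weekday = cosine_curve(10, 3, 0)
        weekend = cosine_curve(10, 1, 0, daytype="weekend")
        assert amr_contrast_from_curves(weekday, weekend) == pytest.approx(
            -0.4, abs=1e-9)

    def test_doubling_both_curves_invariant(self):
        weekday = cosine_curve(10, 3, 0)
        weekend = cosine_curve(10, 1, 0, daytype="weekend")
        c0 = amr_contrast_from_curves(weekday, weekend)
        double = lambda c: DiurnalCurve(c.daytype, c.grid, 2 * c.values)
        assert amr_contrast_from_curves(double(weekday), double(weekend)) == (
            pytest.approx(c0, abs=1e-12))


class TestBandsAndFormatting:
    def test_published_morning_pair_lands_in_first_band(self):
        # 04:35 vs 05:38 -> just over an hour apart
        assert median_diff_band(4 + 35 / 60, 5 + 38 / 60) == "0-2"

    def test_wide_pair_uses_shorter_arc(self):
        # 13:24 vs 00:13: shorter arc is 10.8 h, not 13.2 h
        assert median_diff_band(13 + 24 / 60, 0 + 13 / 60) == "10-12"

    def test_identical_times(self):
        assert median_diff_band(7.5, 7.5) == "0-2"

    def test_format_clock(self):
        assert format_clock(4 + 35 / 60) == "04:35"
        assert format_clock(0.0) == "00:00"
        assert format_clock(23.999) == "00:00"  # rounds up and wraps


class TestPolarNormalize:
    def test_divides_by_minimum(self):
        np.testing.assert_allclose(polar_normalize([2, 4, 8]), [1, 2, 4])

    def test_constant_maps_to_ones(self):
        np.testing.assert_allclose(polar_normalize([3.0] * 24), 1.0)

    @given(st.lists(st.floats(min_value=0.5, max_value=100), min_size=24,
                    max_size=24))
    def test_minimum_is_exactly_one(self, values):
        assert polar_normalize(values).min() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_minimum_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            polar_normalize([0.0, 1.0])
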