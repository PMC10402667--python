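"""GDSA core: normalization, generalized gradient, segmentation, statistic."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from oracles import brute_force_gradient, brute_force_regions

from gdsaqa import synthetic_data as sd
from gdsaqa.epid_io import CompositeImage, PatientSeries
from gdsaqa.exceptions import (
    DegenerateRoiError,
    EmptyDeliveryError,
    GeometryMismatchError,
)
from gdsaqa.gdsa_core import (
    analyze_series,
    dose_difference_percent,
    gdsa_statistic,
    gradient_map,
    normalize_to_percent,
    segment_regions,
)


def comp(pixels, pitch=0.336, frac=1):
    return CompositeImage(np.asarray(pixels, float), pitch, frac)


class TestNormalize:
    def test_definition(self):
        out = normalize_to_percent(comp([[1, 2], [4, 4]]))
        np.testing.assert_allclose(out, [[25, 50], [100, 100]])

    def test_constant_image_is_all_100(self):
        out = normalize_to_percent(comp(3.7 * np.ones((4, 4))))
        np.testing.assert_allclose(out, 100.0)

    def test_all_zero_rejected(self):
        with pytest.raises(EmptyDeliveryError):
            normalize_to_percent(comp(np.zeros((3, 3))))


class TestGradientMap:
    def test_constant_is_zero(self):
        g = gradient_map(50 * np.ones((6, 6)), 0.336)
        np.testing.assert_array_equal(g.values, 0.0)

    def test_linear_ramp_closed_form(self):
        # d = g * column (percent per pixel): interior pixels see two
        # horizontal neighbours at +/-g and two vertical at 0, so
        # G = sqrt(2 g^2) / pitch = g * sqrt(2) / pitch.
        g_per_px, pitch = 4.0, 0.336
        d = np.tile(g_per_px * np.arange(5.0), (5, 1))
        g = gradient_map(d, pitch)
        expected = g_per_px * math.sqrt(2) / pitch
        np.testing.assert_allclose(g.values[1:-1, 1:-1], expected, rtol=1e-12)
        # left border (one horizontal neighbour): G = g / pitch
        np.testing.assert_allclose(
            g.values[1:-1, 0], g_per_px / pitch, rtol=1e-12
        )

    @pytest.mark.parametrize("reduction", ["sum", "mean"])
    def test_matches_brute_force_oracle(self, rng, reduction):
        for _ in range(20):
            d = rng.uniform(0, 100, (32, 32))
            ours = gradient_map(d, 0.336, reduction=reduction).values
            ref = brute_force_gradient(d, 0.336, reduction)
            np.testing.assert_allclose(ours, ref, rtol=1e-12, atol=1e-12)

    def test_shift_invariance_and_linear_scaling(self, rng):
        d = rng.uniform(0, 100, (16, 16))
        base = gradient_map(d, 0.336).values
        shifted = gradient_map(d + 17.3, 0.336).values
        scaled = gradient_map(2.5 * d, 0.336).values
        np.testing.assert_allclose(shifted, base, rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(scaled, 2.5 * base, rtol=1e-12)

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValueError):
            gradient_map(np.ones((1, 5)), 0.336)


class TestSegmentation:
    def test_plateau_pixel_is_high_dose_low_gradient(self):
        ref = 100 * np.ones((4, 4))
        masks = segment_regions(ref, gradient_map(ref, 0.336))
        assert masks.high_dose_low_gradient.all()

    def test_toy_masks_match_exhaustive_classification(self, rng):
        # values straddling both thresholds, including exact ties
        ref = rng.uniform(0, 10, (5, 5))
        ref.flat[[3, 7, 12]] = 5.0  # dose exactly at threshold -> high dose
        grad = gradient_map(ref, 0.336)
        grad.values.flat[4] = 3.0  # gradient at threshold -> high gradient
        masks = segment_regions(ref, grad)
        expected = brute_force_regions(ref, grad.values, 5.0, 3.0)
        for name, exp in expected.items():
            np.testing.assert_array_equal(getattr(masks, name), exp)

    def test_mismatched_dimensions(self):
        with pytest.raises(GeometryMismatchError):
            segment_regions(np.ones((3, 3)), gradient_map(np.ones((4, 4)), 1.0))

    @settings(max_examples=50, derandomize=True)
    @given(
        ref=hnp.arrays(
            float,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=12),
            elements=st.floats(0, 120),
        )
    )
    def test_masks_always_partition_the_image(self, ref):
        masks = segment_regions(ref, gradient_map(ref, 0.336))
        stack = np.stack(
            [
                masks.high_dose_low_gradient,
                masks.high_dose_high_gradient,
                masks.low_dose_low_gradient,
                masks.low_dose_high_gradient,
            ]
        )
        assert (stack.sum(axis=0) == 1).all()


class TestDoseDifference:
    def test_identity_is_zero(self):
        ref = comp([[1, 2], [3, 4]])
        np.testing.assert_array_equal(
            dose_difference_percent(ref, ref), np.zeros((2, 2))
        )

    def test_uniform_scaling_closed_form(self):
        ref = comp([[1, 2], [3, 4]])
        hot = comp(1.02 * ref.pixels)
        diff = dose_difference_percent(ref, hot)
        np.testing.assert_allclose(diff, 100 * 0.02 * ref.pixels / 4.0)
        assert diff[1, 1] == pytest.approx(2.0)

    def test_direct_arithmetic(self):
        diff = dose_difference_percent(
            comp([[1, 2], [2, 4]]), comp([[1, 2], [2, 5]])
        )
        np.testing.assert_allclose(diff, [[0, 0], [0, 25]])

    def test_geometry_mismatch(self):
        with pytest.raises(GeometryMismatchError):
            dose_difference_percent(comp(np.ones((2, 2))), comp(np.ones((3, 3))))


class TestGdsaStatistic:
    def _plateau_masks(self, shape):
        ref = 100 * np.ones(shape)
        return segment_regions(ref, gradient_map(ref, 0.336))

    def test_zero_difference(self):
        masks = self._plateau_masks((4, 4))
        res = gdsa_statistic(np.zeros((4, 4)), masks)
        assert (res.gdsa_mean_pct, res.gdsa_std_pct) == (0.0, 0.0)
        assert res.roi_pixel_count == 16
        assert not res.flagged

    @staticmethod
    def _masks_with_roi(roi):
        from gdsaqa.gdsa_core import RegionMasks

        empty = np.zeros_like(roi)
        return RegionMasks(roi, empty, ~roi, empty)

    def test_hand_computed_mean_and_std(self):
        # six ROI pixels valued 1..6: mean 3.5, population variance
        # ((2.5^2+1.5^2+0.5^2)*2)/6 = 35/12
        diff = np.zeros((5, 5))
        roi = np.zeros((5, 5), dtype=bool)
        roi[0, :3] = roi[1, :3] = True
        diff[0, :3] = [1, 2, 3]
        diff[1, :3] = [4, 5, 6]
        res = gdsa_statistic(diff, self._masks_with_roi(roi))
        assert res.gdsa_mean_pct == pytest.approx(3.5)
        assert res.gdsa_std_pct == pytest.approx(math.sqrt(35 / 12))
        assert res.roi_pixel_count == 6

    def test_empty_roi_is_an_error_not_zero(self):
        masks = self._masks_with_roi(np.zeros((3, 3), dtype=bool))
        with pytest.raises(DegenerateRoiError):
            gdsa_statistic(np.zeros((3, 3)), masks)

    @pytest.mark.parametrize("alpha", [0.005, 0.01, 0.02, 0.035])
    def test_uniform_gain_closed_form_on_plateau(self, small_reference, alpha):
        hot = CompositeImage(
            (1 + alpha) * small_reference.pixels,
            small_reference.pixel_pitch_mm,
            2,
        )
        masks = sd.reference_roi_mask(small_reference)
        diff = dose_difference_percent(small_reference, hot)
        res = gdsa_statistic(diff, masks)
        expected = sd.expected_gdsa_mean(small_reference, alpha)
        assert res.gdsa_mean_pct == pytest.approx(expected, abs=1e-9)

    def test_swap_negates_with_equal_maxima(self, rng):
        a = rng.uniform(1, 2, (8, 8))
        peak = a.max()
        b = a.copy()
        b[0, 0], b[-1, -1] = 0.5, peak  # keep maxima equal
        ca, cb = comp(a), comp(b)
        masks = self._plateau_masks((8, 8))
        fwd = gdsa_statistic(dose_difference_percent(ca, cb), masks)
        rev = gdsa_statistic(dose_difference_percent(cb, ca), masks)
        assert fwd.gdsa_mean_pct == pytest.approx(-rev.gdsa_mean_pct, abs=1e-12)


class TestAnalyzeSeries:
    def test_identical_composites_never_flag(self, small_reference):
        comps = [
            CompositeImage(small_reference.pixels, 0.336, i) for i in (1, 2, 3)
        ]
        results = analyze_series(PatientSeries("p", comps))
        assert [r.gdsa_mean_pct for r in results] == [0.0, 0.0, 0.0]
        assert not any(r.flagged for r in results)

    def test_plateau_scaled_above_threshold_is_flagged(self, small_reference):
        hot = CompositeImage(1.035 * small_reference.pixels, 0.336, 2)
        results = analyze_series(PatientSeries("p", [small_reference, hot]))
        assert results[1].flagged
        assert results[1].gdsa_mean_pct == pytest.approx(
            sd.expected_gdsa_mean(small_reference, 0.035), abs=1e-9
        )

    def test_strictly_increasing_gain_gives_strictly_increasing_series(
        self, small_reference
    ):
        alphas = [0.0, 0.004, 0.011, 0.02, 0.033]
        comps = [
            CompositeImage((1 + a) * small_reference.pixels, 0.336, i + 1)
            for i, a in enumerate(alphas)
        ]
        means = [
            r.gdsa_mean_pct for r in analyze_series(PatientSeries("p", comps))
        ]
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_mismatched_fraction_reported_not_fatal(self, small_reference):
        bad = CompositeImage(np.ones((10, 10)), 0.336, 2)
        ok = CompositeImage(1.01 * small_reference.pixels, 0.336, 3)
        results = analyze_series(PatientSeries("p", [small_reference, bad, ok]))
        assert math.isnan(results[1].gdsa_mean_pct)
        assert results[1].note is not None
        assert not results[1].flagged
        assert results[2].gdsa_mean_pct == pytest.approx(
            sd.expected_gdsa_mean(small_reference, 0.01), abs=1e-9
        )
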