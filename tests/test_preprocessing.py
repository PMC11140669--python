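"""Preprocessing operations: contracts, oracles, and invariants."""

import numpy as np
import pytest

from ramankit import (
    baseline_asls,
    baseline_aspls,
    crop,
    denoise_gaussian,
    denoise_savgol,
    despike_whitaker_hayes,
    flatten,
    make_container,
    normalize,
    subtract_background,
    unflatten,
)
from ramankit.core import RangeError
from ramankit.preprocessing import (
    AlignmentError,
    DegenerateRangeError,
    ParameterError,
)
from conftest import make_smooth_spectra


class TestCrop:
    def test_fingerprint_region_boundaries_inclusive(self, wide_axis):
        c = make_container(np.ones((3, wide_axis.size)), wide_axis)
        out = crop(c, 700, 1800)
        assert out.axis.values[0] == 700.0
        assert out.axis.values[-1] == 1800.0
        assert np.all((out.axis.values >= 700) & (out.axis.values <= 1800))
        assert out.spatial_shape == (3,)

    def test_full_range_crop_is_identity(self, smooth_stack):
        out = crop(smooth_stack, smooth_stack.axis.values[0], smooth_stack.axis.values[-1])
        assert out == smooth_stack

    def test_single_band_crop(self):
        c = make_container(np.array([1.0, 2.0, 3.0]), [1, 2, 3])
        out = crop(c, 2, 2.5)
        np.testing.assert_array_equal(out.axis.values, [2.0])

    def test_empty_intersection_raises(self):
        c = make_container(np.zeros(3), [1, 2, 3])
        with pytest.raises(RangeError):
            crop(c, 10, 20)


class TestDespike:
    def test_spike_on_constant_flagged_and_replaced(self):
        # hand oracle: y = 1 everywhere, spike to 100 at index 10, B = 64.
        # diffs are 99 at positions 9 and -99 at 10, else 0; MAD = 0 so the
        # mean-absolute-deviation fallback gives 2*99/63, hence
        # |Z| = 0.6745 * 63 / 2 = 21.2 >> 6.5 at the spike edges.
        y = np.ones(64)
        y[10] = 100.0
        c = make_container(y, np.arange(64.0))
        out, mask = despike_whitaker_hayes(c, return_mask=True)
        assert mask[10]
        assert out.intensities[10] == 1.0
        untouched = np.ones(64, bool)
        untouched[mask] = False
        np.testing.assert_array_equal(out.intensities[untouched], y[untouched])
        # replacement neighbors are the exact constant
        np.testing.assert_array_equal(out.intensities, np.ones(64))

    def test_clean_smooth_spectra_unaltered(self, fingerprint_axis):
        rng = np.random.default_rng(21)
        data = make_smooth_spectra(rng, 5, fingerprint_axis, noise_sigma=0.02)
        c = make_container(data, fingerprint_axis)
        out, mask = despike_whitaker_hayes(c, return_mask=True)
        assert mask.mean() < 1e-3
        altered = np.mean(out.intensities != data)
        assert altered < 1e-3

    def test_constant_spectrum_is_identity(self):
        c = make_container(np.full((2, 32), 3.5), np.arange(32.0))
        out = despike_whitaker_hayes(c)
        np.testing.assert_array_equal(out.intensities, c.intensities)

    def test_idempotent_on_despiked_fixtures(self):
        y = np.ones((3, 64))
        y[0, 10] = 50.0
        y[1, 40] = 120.0
        c = make_container(y, np.arange(64.0))
        once = despike_whitaker_hayes(c)
        twice = despike_whitaker_hayes(once)
        assert twice == once

    def test_recall_and_false_positive_rates(self, fingerprint_axis):
        rng = np.random.default_rng(77)
        n = 200
        clean = make_smooth_spectra(rng, n, fingerprint_axis, noise_sigma=0.02)
        mask = rng.random(clean.shape) < 0.002
        spiked = clean.copy()
        spiked[mask] += rng.uniform(5, 10, size=mask.sum()) * clean.max()
        out, flagged = despike_whitaker_hayes(
            make_container(spiked, fingerprint_axis), return_mask=True
        )
        recall = (flagged & mask).sum() / mask.sum()
        assert recall >= 0.95

    def test_parameter_validation(self, smooth_stack):
        with pytest.raises(ParameterError):
            despike_whitaker_hayes(smooth_stack, z_threshold=-1)
        with pytest.raises(ParameterError):
            despike_whitaker_hayes(smooth_stack, window=4)


class TestSavgol:
    @pytest.mark.parametrize("order,window", [(3, 7), (3, 9), (2, 5), (4, 11)])
    def test_reproduces_polynomials_exactly(self, order, window):
        i = np.arange(200.0)
        rng = np.random.default_rng(order * window)
        coeffs = rng.uniform(-1, 1, order + 1)
        y = np.polynomial.polynomial.polyval(i / 100.0, coeffs)
        c = make_container(y, i + 400)
        out = denoise_savgol(c, polyorder=order, window=window)
        np.testing.assert_allclose(out.intensities, y, rtol=1e-10, atol=1e-12)

    def test_constant_is_fixed_point(self):
        c = make_container(np.full(50, 2.0), np.arange(50.0))
        out = denoise_savgol(c, 3, 7)
        np.testing.assert_allclose(out.intensities, 2.0, rtol=1e-13)

    def test_reduces_noise_on_cubic(self):
        rng = np.random.default_rng(4)
        i = np.arange(500.0)
        clean = 1 + 0.01 * i - 2e-5 * i**2 + 1e-8 * i**3
        noisy = clean + 0.1 * rng.standard_normal(500)
        out = denoise_savgol(make_container(noisy, i), 3, 9)
        rmse_out = np.sqrt(np.mean((out.intensities - clean) ** 2))
        rmse_in = np.sqrt(np.mean((noisy - clean) ** 2))
        assert rmse_out < rmse_in

    def test_window_validation(self):
        c = make_container(np.zeros(5), np.arange(5.0))
        with pytest.raises(ParameterError):
            denoise_savgol(c, 3, 7)  # window > B
        with pytest.raises(ParameterError):
            denoise_savgol(c, 5, 5)  # order >= window


class TestGaussianDenoise:
    def test_constant_preserved(self):
        c = make_container(np.full((2, 40), 7.0), np.arange(40.0))
        out = denoise_gaussian(c, 2.0)
        np.testing.assert_allclose(out.intensities, 7.0, rtol=1e-12)

    def test_impulse_spreads_to_unit_sum_kernel(self):
        y = np.zeros(201)
        y[100] = 1.0
        out = denoise_gaussian(make_container(y, np.arange(201.0)), 3.0)
        assert out.intensities.sum() == pytest.approx(1.0, abs=1e-10)
        assert out.intensities[100] == out.intensities.max()

    def test_reduces_noise_variance(self):
        rng = np.random.default_rng(12)
        i = np.arange(400.0)
        clean = np.sin(i / 60.0) + 2
        noisy = clean + 0.1 * rng.standard_normal(400)
        out = denoise_gaussian(make_container(noisy, i), 1.5)
        assert np.var(out.intensities - clean) < np.var(noisy - clean)


class TestBaselines:
    def test_asls_removes_straight_line(self, fingerprint_axis):
        t = np.linspace(0, 1, fingerprint_axis.size)
        line = 2.0 + 5.0 * t
        out = baseline_asls(make_container(line, fingerprint_axis))
        rms = np.sqrt(np.mean(out.intensities**2))
        assert rms < 0.01 * 5.0

    def test_asls_zero_input_zero_output(self, fingerprint_axis):
        out = baseline_asls(make_container(np.zeros(fingerprint_axis.size), fingerprint_axis))
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-12)

    def test_asls_preserves_peak_on_line(self, fingerprint_axis):
        t = np.linspace(0, 1, fingerprint_axis.size)
        line = 2.0 + 5.0 * t
        peak = 3.0 * np.exp(-((fingerprint_axis - 1200.0) ** 2) / (2 * 8.0**2))
        out, base = baseline_asls(
            make_container(line + peak, fingerprint_axis), return_baseline=True
        )
        assert out.intensities.max() == pytest.approx(3.0, rel=0.1)
        # baseline under the peak stays close to the line
        peak_region = np.abs(fingerprint_axis - 1200.0) < 30
        assert np.max(np.abs(base.intensities[peak_region] - line[peak_region])) < 0.3

    def test_asls_large_lambda_approaches_line(self, fingerprint_axis):
        # second differences of the fitted baseline vanish as lam grows
        rng = np.random.default_rng(3)
        y = make_smooth_spectra(rng, 1, fingerprint_axis)[0] + np.linspace(1, 4, fingerprint_axis.size)
        _, base = baseline_asls(
            make_container(y, fingerprint_axis), lam=1e12, return_baseline=True
        )
        d2 = np.diff(base.intensities, n=2)
        assert np.max(np.abs(d2)) < 1e-6

    def test_aspls_zero_input_zero_output(self, fingerprint_axis):
        out = baseline_aspls(make_container(np.zeros(fingerprint_axis.size), fingerprint_axis))
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-12)

    def test_aspls_smooth_baseline_residual_small(self, fingerprint_axis):
        t = np.linspace(0, 1, fingerprint_axis.size)
        cubic = 1.0 + 3 * t - 4 * t**2 + 2.5 * t**3
        amp = cubic.max() - cubic.min()
        out = baseline_aspls(make_container(cubic, fingerprint_axis))
        assert np.sqrt(np.mean(out.intensities**2)) < 0.02 * amp

    def test_aspls_negative_excursions_bounded(self, fingerprint_axis):
        t = np.linspace(0, 1, fingerprint_axis.size)
        line = 2.0 + 5.0 * t
        peak = 3.0 * np.exp(-((fingerprint_axis - 1200.0) ** 2) / (2 * 8.0**2))
        out = baseline_aspls(make_container(line + peak, fingerprint_axis))
        assert out.intensities.min() >= -1e-3  # noiseless fixture
        assert out.intensities.max() == pytest.approx(3.0, rel=0.1)

    def test_lambda_and_p_validated(self, smooth_stack):
        with pytest.raises(ParameterError):
            baseline_asls(smooth_stack, lam=-1)
        with pytest.raises(ParameterError):
            baseline_asls(smooth_stack, p=1.5)
        with pytest.raises(ParameterError):
            baseline_aspls(smooth_stack, lam=0)


class TestNormalize:
    def test_minmax_global_hits_zero_and_one(self, random_image):
        out = normalize(random_image, "minmax_global")
        assert out.intensities.min() == 0.0
        assert out.intensities.max() == 1.0

    def test_minmax_pixel_small_example(self):
        c = make_container(np.array([2.0, 4.0, 6.0]), [1, 2, 3])
        out = normalize(c, "minmax_pixel")
        np.testing.assert_allclose(out.intensities, [0.0, 0.5, 1.0])

    def test_auc_pixel_unit_trapezoid_integral(self, smooth_stack):
        out = normalize(smooth_stack, "auc_pixel")
        flat, _ = flatten(out)
        areas = np.trapezoid(flat, x=out.axis.values, axis=1)
        np.testing.assert_allclose(areas, 1.0, atol=1e-12)

    def test_degenerate_inputs_name_the_pixel(self):
        c = make_container(np.vstack([np.ones(4), np.arange(4.0)]), np.arange(4.0))
        with pytest.raises(DegenerateRangeError, match="pixel 0"):
            normalize(c, "minmax_pixel")
        c2 = make_container(np.full((2, 4), 5.0), np.arange(4.0))
        with pytest.raises(DegenerateRangeError):
            normalize(c2, "minmax_global")


class TestSubtractBackground:
    def test_self_subtraction_gives_zero(self, fingerprint_axis):
        rng = np.random.default_rng(6)
        y = rng.random(fingerprint_axis.size)
        c = make_container(y, fingerprint_axis)
        out = subtract_background(c, c)
        np.testing.assert_array_equal(out.intensities, 0.0)

    def test_zero_background_is_identity(self, smooth_stack):
        bg = make_container(
            np.zeros(smooth_stack.n_bands), smooth_stack.axis.values
        )
        assert subtract_background(smooth_stack, bg) == smooth_stack

    def test_recovers_signal_exactly(self, fingerprint_axis):
        rng = np.random.default_rng(9)
        signal = rng.random((4, 4, fingerprint_axis.size))
        bg = rng.random(fingerprint_axis.size)
        c = make_container(signal + bg, fingerprint_axis)
        out = subtract_background(c, make_container(bg, fingerprint_axis))
        np.testing.assert_allclose(out.intensities, signal, atol=1e-12)

    def test_axis_mismatch_rejected(self, smooth_stack):
        bg = make_container(np.zeros(10), np.arange(10.0))
        with pytest.raises(AlignmentError):
            subtract_background(smooth_stack, bg)


@pytest.mark.parametrize(
    "op",
    [
        lambda c: despike_whitaker_hayes(c),
        lambda c: denoise_savgol(c, 3, 7),
        lambda c: denoise_gaussian(c, 1.0),
        lambda c: baseline_asls(c),
        lambda c: normalize(c, "minmax_pixel"),
        lambda c: normalize(c, "auc_pixel"),
    ],
    ids=["despike", "savgol", "gaussian", "asls", "minmax_pixel", "auc_pixel"],
)
def test_per_spectrum_ops_commute_with_flatten(op, fingerprint_axis):
    """Applying an operation to an image equals applying it to each row of
    the flattened matrix — and never mutates the input."""
    rng = np.random.default_rng(31)
    data = make_smooth_spectra(rng, 6, fingerprint_axis, noise_sigma=0.02).reshape(
        3, 2, -1
    ) + 0.1
    c = make_container(data, fingerprint_axis)
    snapshot = c.intensities.copy()
    out_image = op(c)
    matrix, spatial = flatten(c)
    out_rows = op(unflatten(matrix, (matrix.shape[0],), c.axis))
    np.testing.assert_array_equal(
        out_image.intensities.reshape(-1, out_image.n_bands), out_rows.intensities
    )
    np.testing.assert_array_equal(c.intensities, snapshot)
    assert out_image.intensities.shape == c.intensities.shape
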