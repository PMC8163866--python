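"""Pre-processing: absorbance referencing, transfer functions, TV denoising,
normalisation, cube smoothing/restriction, image alignment."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirscan import (
    FtirConfig,
    ScannerConfig,
    normalize_image,
    preprocess_cube,
    simulate_ftir,
    simulate_mir_scan,
    threshold_adjust,
    to_absorbance,
    tv_denoise_adaptive,
)
from mirscan.acquisition import HyperCube
from mirscan.errors import ConfigurationError, DataError
from mirscan.preprocess import AbsorbanceImage, align_images, estimate_noise_sd


def img(values, nu=2926.0, pitch=20.0):
    return AbsorbanceImage(np.asarray(values, dtype=float), nu, pitch)


class TestToAbsorbance:
    def test_equal_intensity_gives_zero(self):
        i = np.full((5, 5), 0.7)
        assert np.allclose(to_absorbance(i, i).values, 0.0)

    def test_decade_attenuation_gives_unit_absorbance(self):
        bg = np.full((5, 5), 0.7)
        assert np.allclose(to_absorbance(bg / 10, bg).values, 1.0)

    def test_recovers_phantom_absorbance_from_noiseless_scan(self, brain_phantom):
        scan = simulate_mir_scan(brain_phantom, ScannerConfig(noise_sd=0.0), seed=0)
        for laser in scan.config.lasers:
            a = to_absorbance(scan.images[laser.id], scan.background[laser.id])
            expected = brain_phantom.absorbance_map(laser.wavenumber)
            assert np.allclose(a.values, expected, atol=1e-9)

    def test_nonpositive_background_identifies_pixel(self):
        bg = np.ones((3, 3))
        bg[1, 2] = 0.0
        with pytest.raises(DataError, match=r"\(1, 2\)"):
            to_absorbance(np.ones((3, 3)), bg)

    def test_floor_clips_negative_absorbance(self):
        bg = np.ones((3, 3))
        out = to_absorbance(bg * 2.0, bg, floor=0.0)  # I > I_bg -> negative A
        assert np.all(out.values >= 0.0)


class TestThresholdAdjust:
    def test_unit_gain_is_identity(self):
        x = img(np.random.default_rng(0).random((10, 10)))
        assert np.allclose(threshold_adjust(x, 25.0, 1.0).values, x.values)

    def test_constant_image_unchanged(self):
        x = img(np.full((8, 8), 0.4))
        assert np.allclose(threshold_adjust(x, 25.0, 2.0).values, 0.4)

    def test_two_level_transfer_oracle(self):
        # below-threshold level amplified by the gain, above unchanged
        x = img(np.array([[0.1, 0.8], [0.1, 0.8]]))
        out = threshold_adjust(x, 50.0, 2.0, threshold=0.5)
        assert np.allclose(out.values[:, 0], 0.2)
        assert np.allclose(out.values[:, 1], 0.8)

    @given(gain=st.floats(1.0, 5.0), t=st.floats(0.1, 0.9))
    def test_transfer_is_monotone_and_continuous(self, gain, t):
        xs = np.linspace(0.0, 1.0, 501).reshape(1, -1)
        out = threshold_adjust(img(xs), 50.0, gain, threshold=t).values.ravel()
        assert np.all(np.diff(out) >= -1e-12)  # monotone
        assert np.max(np.abs(np.diff(out))) < gain * 0.01  # no jumps
        assert np.allclose(out[xs.ravel() >= t], xs.ravel()[xs.ravel() >= t])


class TestTvDenoise:
    def test_zero_strength_is_identity(self, rng):
        x = img(rng.random((20, 20)))
        assert np.allclose(tv_denoise_adaptive(x, 0.0).values, x.values)

    def test_constant_image_unchanged(self):
        x = img(np.full((20, 20), 0.3))
        assert np.allclose(tv_denoise_adaptive(x, 0.5).values, 0.3)

    def test_step_edge_noise_reduced_edge_retained(self):
        rng = np.random.default_rng(0)
        clean = np.zeros((100, 100))
        clean[:, 50:] = 1.0
        noisy = clean + 0.1 * rng.standard_normal(clean.shape)
        out = tv_denoise_adaptive(img(noisy), strength=0.3).values
        # flat-region noise variance reduced by at least half
        assert out[:, :40].var() <= 0.5 * noisy[:, :40].var()
        # 50%-crossing of the edge moves at most one pixel per row
        mid = 0.5 * (out[:, :40].mean() + out[:, 60:].mean())
        crossings = np.argmax(out > mid, axis=1)
        assert np.abs(crossings - 50).max() <= 1

    def test_output_within_input_range(self, rng):
        x = img(rng.random((30, 30)))
        out = tv_denoise_adaptive(x, 0.4).values
        assert out.min() >= x.values.min() - 1e-12
        assert out.max() <= x.values.max() + 1e-12

    def test_even_window_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            tv_denoise_adaptive(img(rng.random((10, 10))), 0.1, adapt_window=4)


class TestNoiseEstimate:
    def test_tracks_gaussian_noise_level(self, rng):
        x = 0.1 * rng.standard_normal((200, 200))
        assert estimate_noise_sd(x) == pytest.approx(0.1, rel=0.05)

    def test_zero_for_piecewise_constant(self):
        x = np.zeros((50, 50))
        x[:, 25:] = 1.0
        assert estimate_noise_sd(x) == 0.0


class TestNormalize:
    def test_full_percentiles_map_to_unit_interval(self):
        x = img(np.linspace(2.0, 4.0, 100).reshape(10, 10))
        out = normalize_image(x, 0.0, 100.0).values
        assert out.min() == pytest.approx(0.0)
        assert out.max() == pytest.approx(1.0)

    def test_idempotent_at_same_percentiles(self, rng):
        x = img(rng.random((20, 20)))
        once = normalize_image(x, 0.0, 100.0)
        twice = normalize_image(once, 0.0, 100.0)
        assert np.allclose(once.values, twice.values)

    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(1)
        x = rng.random((15, 15))
        n1 = normalize_image(img(x), 5.0, 95.0).values
        n2 = normalize_image(img(a * x + b), 5.0, 95.0).values
        assert np.allclose(n1, n2, atol=1e-10)

    def test_degenerate_image_rejected(self):
        with pytest.raises(DataError):
            normalize_image(img(np.full((5, 5), 0.3)), 1.0, 99.0)


class TestPreprocessCube:
    def cube(self, data, wn):
        return HyperCube(np.asarray(data, float), np.asarray(wn, float), 20.0)

    def test_unit_norm_with_full_axis(self, rng):
        c = self.cube(rng.random((4, 4, 10)) + 0.1, np.linspace(4000, 3000, 10))
        out = preprocess_cube(c, smooth_window=1, ranges=[(2900, 4100)])
        norms = np.linalg.norm(out.data, axis=2)
        assert np.allclose(norms, 1.0)

    def test_constant_spectrum_survives_smoothing(self):
        c = self.cube(np.full((3, 3, 21), 0.5), np.linspace(4000, 3000, 21))
        out = preprocess_cube(c, smooth_window=5, ranges=[(2900, 4100)])
        assert np.allclose(out.data, out.data[0, 0, 0])

    def test_default_range_restriction_channel_count(self, brain_phantom):
        cfg = FtirConfig(pixel_pitch=20.0, noise_sd=0.0)
        cube = simulate_ftir(brain_phantom, cfg, seed=0)
        out = preprocess_cube(cube, smooth_window=1)
        # enumeration oracle on the 4000 -> 752 cm-1, 8 cm-1 axis
        axis = cfg.axis()
        expected = int(
            (((axis >= 750) & (axis <= 1500)) | ((axis >= 2500) & (axis <= 4000))).sum()
        )
        assert out.shape[2] == expected == 282

    def test_empty_restriction_rejected(self, rng):
        c = self.cube(rng.random((3, 3, 5)), np.linspace(4000, 3900, 5))
        with pytest.raises(ConfigurationError):
            preprocess_cube(c, smooth_window=1, ranges=[(750, 1500)])

    def test_norm_floor_zeroes_noise_only_pixels(self, rng):
        data = np.zeros((4, 4, 20))
        data[:2] = 1.0  # strong spectra in half the pixels
        data[2:] = 0.001 * rng.standard_normal((2, 4, 20))
        c = self.cube(data, np.linspace(4000, 3000, 20))
        out = preprocess_cube(c, smooth_window=1, ranges=[(2900, 4100)],
                              norm_floor_fraction=0.25)
        assert np.allclose(out.data[2:], 0.0)
        assert np.allclose(np.linalg.norm(out.data[:2], axis=2), 1.0)


class TestAlign:
    def test_identical_images_zero_shift(self, rng):
        x = rng.random((40, 40))
        res = align_images([x, x.copy()])
        assert res.shifts[1] == (0.0, 0.0)
        assert res.ok == [True, True]

    def test_constructed_shift_recovered(self):
        from scipy.ndimage import gaussian_filter

        base = gaussian_filter(np.random.default_rng(0).random((60, 60)), 3)
        moved = np.roll(base, (3, -2), axis=(0, 1))
        res = align_images([base, moved])
        assert tuple(abs(s) for s in res.shifts[1]) == (3.0, 2.0)
        interior = np.s_[5:-5, 5:-5]
        assert np.allclose(res.images[1][interior], base[interior], atol=1e-6)

    def test_pure_noise_pair_flags_failure_and_keeps_input(self):
        rng = np.random.default_rng(7)
        a, b = rng.standard_normal((80, 80)), rng.standard_normal((80, 80))
        res = align_images([a, b])
        assert res.ok == [True, False]
        assert np.array_equal(res.images[1], b)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(DataError):
            align_images([rng.random((10, 10)), rng.random((12, 10))])
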