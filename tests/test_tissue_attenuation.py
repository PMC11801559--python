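import math

import numpy as np
import pytest

from radenhance.raster_io import NormalizedImage
from radenhance.tissue_attenuation import (
    AttenuationMaps,
    ContrastParams,
    LocalExtrema,
    apply_contrast_enhancement,
    brightness_exponent,
    compute_local_extrema,
    removable_component,
    removable_factor,
    run_contrast_stage,
)


def sliding_extrema_oracle(values, window):
    """Naive double-loop windowed min/max with replicate padding."""
    h, w = values.shape
    r = window // 2
    padded = np.pad(values, r, mode="edge")
    mx = np.empty_like(values)
    mn = np.empty_like(values)
    for i in range(h):
        for j in range(w):
            block = padded[i : i + window, j : j + window]
            mx[i, j] = block.max()
            mn[i, j] = block.min()
    return mx, mn


class TestContrastParams:
    @pytest.mark.parametrize("window", [0, 2, -3])
    def test_bad_window(self, window):
        with pytest.raises(ValueError):
            ContrastParams(window=window)

    def test_bad_eps(self):
        with pytest.raises(ValueError):
            ContrastParams(eps=0.0)


class TestLocalExtrema:
    def test_constant_image(self):
        img = NormalizedImage(values=np.full((5, 5), 0.4))
        ext = compute_local_extrema(img, ContrastParams(window=3))
        assert np.all(ext.local_max == 0.4)
        assert np.all(ext.local_min == 0.4)

    def test_single_bright_pixel_replicate_padding(self):
        v = np.zeros((3, 3))
        v[1, 1] = 1.0
        ext = compute_local_extrema(NormalizedImage(values=v), ContrastParams(window=3))
        # derived by brute-force sliding window: center pixel reaches every window
        assert np.all(ext.local_max == 1.0)
        assert np.all(ext.local_min == 0.0)

    def test_window_one_is_identity(self, random_normalized):
        img = random_normalized()
        ext = compute_local_extrema(img, ContrastParams(window=1))
        np.testing.assert_array_equal(ext.local_max, img.values)
        np.testing.assert_array_equal(ext.local_min, img.values)

    @pytest.mark.parametrize("window", [3, 5, 7])
    def test_against_double_loop_oracle(self, random_normalized, window):
        img = random_normalized((16, 16))
        ext = compute_local_extrema(img, ContrastParams(window=window))
        mx, mn = sliding_extrema_oracle(img.values, window)
        np.testing.assert_allclose(ext.local_max, mx)
        np.testing.assert_allclose(ext.local_min, mn)

    def test_bounds_input(self, random_normalized):
        img = random_normalized()
        ext = compute_local_extrema(img, ContrastParams(window=5))
        assert np.all(ext.local_min <= img.values + 1e-15)
        assert np.all(img.values <= ext.local_max + 1e-15)

    def test_oversized_window_warns(self):
        img = NormalizedImage(values=np.random.default_rng(0).uniform(size=(4, 4)))
        with pytest.warns(UserWarning):
            compute_local_extrema(img, ContrastParams(window=9))


class TestRemovableFactor:
    def test_zero_variance_gives_beta_one(self):
        ext = LocalExtrema(local_max=np.full((4, 4), 0.6), local_min=np.full((4, 4), 0.6))
        maps = removable_factor(ext, ContrastParams())
        assert maps.t_variance == 0.0
        np.testing.assert_array_equal(maps.beta, np.ones((4, 4)))

    def test_direct_evaluation(self):
        # beta = exp(-G * var / T) with G=1, var=0.04, T=0.5 -> exp(-0.08)
        lm = np.array([[0.5, 0.5], [0.5, 0.9]])
        ext = LocalExtrema(local_max=np.ones((2, 2)), local_min=lm)
        maps = removable_factor(ext, ContrastParams())
        var = np.var(lm, ddof=1)
        np.testing.assert_allclose(maps.beta[0, 0], math.exp(-var / 0.5))
        np.testing.assert_allclose(maps.t_variance, var)

    def test_pinned_value(self):
        # exp(-1.0 * 0.04 / 0.5) = exp(-0.08) = 0.923116...
        assert math.exp(-1.0 * 0.04 / 0.5) == pytest.approx(0.923116, abs=1e-6)

    def test_zero_local_min_clamped_not_nan(self):
        lm = np.array([[0.0, 0.5], [0.5, 0.9]])
        ext = LocalExtrema(local_max=np.ones((2, 2)), local_min=lm)
        maps = removable_factor(ext, ContrastParams(eps=1e-6))
        assert np.all(np.isfinite(maps.beta))
        assert maps.beta[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_beta_in_unit_interval(self, random_normalized):
        img = random_normalized()
        params = ContrastParams(window=3)
        ext = compute_local_extrema(img, params)
        maps = removable_factor(ext, params)
        assert np.all(maps.beta > 0.0) or np.any(maps.beta == 0.0)  # underflow ok
        assert np.all(maps.beta <= 1.0)
        assert np.all(np.isfinite(maps.beta))


class TestRemovableComponent:
    def test_product(self):
        ext = LocalExtrema(local_max=np.ones((2, 2)), local_min=np.full((2, 2), 0.3))
        maps = AttenuationMaps(beta=np.ones((2, 2)))
        maps = removable_component(maps, ext)
        np.testing.assert_allclose(maps.removable, 0.3)

    def test_pinned_product(self):
        ext = LocalExtrema(local_max=np.ones((2, 2)), local_min=np.full((2, 2), 0.5))
        maps = AttenuationMaps(beta=np.full((2, 2), 0.923116))
        maps = removable_component(maps, ext)
        np.testing.assert_allclose(maps.removable, 0.461558, atol=1e-9)

    def test_requires_beta(self):
        ext = LocalExtrema(local_max=np.ones((2, 2)), local_min=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            removable_component(AttenuationMaps(), ext)

    def test_never_exceeds_local_min(self, random_normalized):
        img = random_normalized()
        params = ContrastParams(window=3)
        ext = compute_local_extrema(img, params)
        maps = removable_component(removable_factor(ext, params), ext)
        assert np.all(maps.removable <= ext.local_min + 1e-15)


class TestBrightnessExponent:
    def _maps(self, local_max, removable):
        ext = LocalExtrema(
            local_max=np.asarray(local_max, dtype=float),
            local_min=np.asarray(removable, dtype=float),
        )
        maps = AttenuationMaps(beta=np.ones_like(ext.local_max))
        maps.removable = np.asarray(removable, dtype=float)
        return maps, ext

    def test_zero_removable_gives_zero_psi(self):
        maps, ext = self._maps(np.full((2, 2), 0.8), np.zeros((2, 2)))
        maps = brightness_exponent(maps, ext, ContrastParams())
        np.testing.assert_allclose(maps.psi, 0.0, atol=1e-15)

    def test_local_max_one_convention(self):
        maps, ext = self._maps(np.ones((2, 2)), np.full((2, 2), 0.2))
        maps = brightness_exponent(maps, ext, ContrastParams())
        np.testing.assert_array_equal(maps.psi, np.ones((2, 2)))

    def test_direct_evaluation(self):
        # G=0.8, R=0.2: arg = 1 - 0.2*0.25 = 0.95; psi = ln(0.95)/ln(0.8)
        maps, ext = self._maps(np.full((2, 2), 0.8), np.full((2, 2), 0.2))
        maps = brightness_exponent(maps, ext, ContrastParams())
        np.testing.assert_allclose(maps.psi, math.log(0.95) / math.log(0.8))
        np.testing.assert_allclose(maps.psi, 0.229867, atol=1e-6)

    def test_finite_and_nonnegative_everywhere(self, random_normalized):
        img = random_normalized()
        params = ContrastParams(window=5)
        ext = compute_local_extrema(img, params)
        maps = removable_component(removable_factor(ext, params), ext)
        maps = brightness_exponent(maps, ext, params)
        assert np.all(np.isfinite(maps.psi))
        assert np.all(maps.psi >= 0.0)


class TestApplyContrastEnhancement:
    def test_identity_when_removable_zero(self, random_normalized):
        img = random_normalized()
        params = ContrastParams(window=5)
        ext = compute_local_extrema(img, params)
        maps = AttenuationMaps(beta=np.zeros(img.shape))
        maps.removable = np.zeros(img.shape)
        maps = brightness_exponent(maps, ext, params)
        out = apply_contrast_enhancement(img, ext, maps, params)
        np.testing.assert_allclose(out.values, img.values, atol=1e-12)

    def test_pinned_pixel(self):
        # I=0.6, R=0.2, G=0.8, psi such that G^psi = 0.95 -> E = 0.4/0.75
        img = NormalizedImage(values=np.full((2, 2), 0.6))
        ext = LocalExtrema(local_max=np.full((2, 2), 0.8), local_min=np.full((2, 2), 0.2))
        maps = AttenuationMaps(beta=np.ones((2, 2)))
        maps.removable = np.full((2, 2), 0.2)
        maps = brightness_exponent(maps, ext, ContrastParams())
        out = apply_contrast_enhancement(img, ext, maps, ContrastParams())
        np.testing.assert_allclose(out.values, 0.4 / 0.75, atol=1e-9)
        np.testing.assert_allclose(out.values, 0.533333, atol=1e-6)

    def test_constant_image_pass_through(self):
        img = NormalizedImage(values=np.full((5, 5), 1.0))
        out, _, _ = run_contrast_stage(img, ContrastParams(window=3))
        np.testing.assert_array_equal(out.values, img.values)

    def test_constant_image_zero_policy(self):
        img = NormalizedImage(values=np.full((5, 5), 1.0))
        out, _, _ = run_contrast_stage(
            img, ContrastParams(window=3, degenerate_policy="zero")
        )
        np.testing.assert_array_equal(out.values, np.zeros((5, 5)))

    def test_zero_point(self):
        # pixels at the removable level map to 0
        img = NormalizedImage(values=np.full((2, 2), 0.2))
        ext = LocalExtrema(local_max=np.full((2, 2), 0.8), local_min=np.full((2, 2), 0.2))
        maps = AttenuationMaps(beta=np.ones((2, 2)))
        maps.removable = np.full((2, 2), 0.2)
        maps = brightness_exponent(maps, ext, ContrastParams())
        out = apply_contrast_enhancement(img, ext, maps, ContrastParams())
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_monotone_in_intensity(self):
        # fixed G, R, psi: E is strictly increasing on [R, G]
        levels = np.linspace(0.2, 0.8, 16).reshape(4, 4)
        img = NormalizedImage(values=levels)
        ext = LocalExtrema(local_max=np.full((4, 4), 0.8), local_min=np.full((4, 4), 0.2))
        maps = AttenuationMaps(beta=np.ones((4, 4)))
        maps.removable = np.full((4, 4), 0.2)
        maps = brightness_exponent(maps, ext, ContrastParams())
        out = apply_contrast_enhancement(img, ext, maps, ContrastParams())
        flat = out.values.ravel()
        assert np.all(np.diff(flat) > 0)


class TestRunContrastStage:
    def test_output_in_range(self, random_normalized):
        img = random_normalized((32, 32))
        out, _, _ = run_contrast_stage(img, ContrastParams(window=7))
        assert np.all(np.isfinite(out.values))
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_window_one_variance_is_image_variance(self, random_normalized):
        img = random_normalized()
        out, ext, maps = run_contrast_stage(img, ContrastParams(window=1))
        np.testing.assert_allclose(maps.t_variance, np.var(img.values, ddof=1))
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_fixed_point_at_local_maxima(self, default_phantom):
        from radenhance.raster_io import normalize

        img = normalize(default_phantom.image)
        out, ext, maps = run_contrast_stage(img, ContrastParams(window=15))
        at_max = img.values == ext.local_max
        np.testing.assert_allclose(
            out.values[at_max], ext.local_max[at_max], atol=1e-9
        )

    def test_intermediates_returned(self, default_phantom):
        from radenhance.raster_io import normalize

        img = normalize(default_phantom.image)
        out, ext, maps = run_contrast_stage(img)
        assert maps.beta is not None
        assert maps.removable is not None
        assert maps.psi is not None
        assert maps.t_variance is not None
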