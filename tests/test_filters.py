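"""Filtering primitives against brute-force oracles and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fgfusion import (
    GuidedFilterParams,
    box_filter,
    fast_guided_filter,
    gaussian_lowpass,
    guided_filter,
    laplacian_filter,
)
from oracles import box_oracle, conv2_oracle, gaussian_kernel_oracle, guided_oracle

small_images = arrays(
    np.float64,
    st.tuples(st.integers(4, 9), st.integers(4, 9)),
    elements=st.floats(0.0, 1.0, allow_nan=False, width=32),
)


class TestBoxFilter:
    def test_constant_preserved(self):
        out = box_filter(np.full((7, 9), 0.37), 2)
        np.testing.assert_allclose(out, 0.37, atol=1e-12)

    def test_impulse_spreads_over_window(self):
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        out = box_filter(img, 1)
        expected = np.zeros((5, 5))
        expected[1:4, 1:4] = 1.0 / 9.0
        np.testing.assert_allclose(out, expected, atol=1e-12)

    @pytest.mark.parametrize("shape,r", [((8, 8), 2), ((16, 16), 1), ((16, 13), 3)])
    def test_matches_window_mean_oracle(self, rng, shape, r):
        img = rng.uniform(0.0, 1.0, shape)
        np.testing.assert_allclose(box_filter(img, r), box_oracle(img, r), atol=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            box_filter(np.zeros((5, 5)), 0)
        with pytest.raises(ValueError):
            box_filter(np.full((5, 5), np.nan), 1)
        with pytest.raises(ValueError):
            box_filter(np.zeros((2, 5)), 1)


class TestLaplacian:
    def test_annihilates_constants_and_ramps(self):
        np.testing.assert_allclose(laplacian_filter(np.full((6, 6), 0.4)), 0.0, atol=1e-12)
        ramp = np.tile(np.arange(8) / 8.0, (8, 1))
        assert np.max(np.abs(laplacian_filter(ramp)[1:-1, 1:-1])) < 1e-12

    def test_impulse_gives_kernel_stencil(self):
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        out = laplacian_filter(img)
        assert out[2, 2] == -4.0
        for di, dj in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
            assert out[2 + di, 2 + dj] == 1.0
        assert out[0, 0] == 0.0


class TestGaussianLowpass:
    def test_constant_preserved(self):
        out = gaussian_lowpass(np.full((12, 12), 0.81), 5, 1.2)
        np.testing.assert_allclose(out, 0.81, atol=1e-12)

    def test_impulse_reproduces_kernel(self):
        img = np.zeros((13, 13))
        img[6, 6] = 1.0
        out = gaussian_lowpass(img, 5, 1.0)
        np.testing.assert_allclose(
            out[4:9, 4:9], gaussian_kernel_oracle(5, 1.0), atol=1e-12
        )

    def test_matches_dense_convolution_oracle(self, rng):
        img = rng.uniform(0.0, 1.0, (16, 16))
        expected = conv2_oracle(img, gaussian_kernel_oracle(11, 5.0))
        np.testing.assert_allclose(gaussian_lowpass(img, 11, 5.0), expected, atol=1e-10)

    def test_rejects_even_size(self):
        with pytest.raises(ValueError):
            gaussian_lowpass(np.zeros((8, 8)), 4, 1.0)


class TestGuidedFilter:
    def test_constant_guide_reduces_to_double_box(self, rng):
        p = rng.uniform(0.0, 1.0, (8, 8))
        guide = np.full((8, 8), 0.6)
        expected = box_filter(box_filter(p, 2), 2)
        np.testing.assert_allclose(guided_filter(p, guide, 2, 0.1), expected, atol=1e-12)

    def test_self_guidance_zero_eps_is_identity(self, rng):
        # every 3x3 window of a random image has positive variance
        guide = rng.uniform(0.0, 1.0, (8, 8))
        np.testing.assert_allclose(guided_filter(guide, guide, 1, 0.0), guide, atol=1e-9)

    def test_matches_literal_regression_oracle(self, rng):
        p = rng.uniform(0.0, 1.0, (6, 6))
        guide = rng.uniform(0.0, 1.0, (6, 6))
        np.testing.assert_allclose(
            guided_filter(p, guide, 1, 0.1), guided_oracle(p, guide, 1, 0.1), atol=1e-12
        )

    @pytest.mark.parametrize("r", [1, 2])
    @pytest.mark.parametrize("eps", [1e-6, 0.1, 0.25])
    def test_oracle_sweep(self, rng, r, eps):
        p = rng.uniform(0.0, 1.0, (8, 8))
        guide = rng.uniform(0.0, 1.0, (8, 8))
        np.testing.assert_allclose(
            guided_filter(p, guide, r, eps), guided_oracle(p, guide, r, eps), atol=1e-9
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(p=small_images, c=st.floats(-2.0, 2.0, allow_nan=False))
    def test_linear_in_input_shift(self, p, c):
        """Adding a constant to the filter input shifts the output by it."""
        rng = np.random.default_rng(5)
        guide = rng.uniform(0.0, 1.0, p.shape)
        base = guided_filter(p, guide, 1, 0.05)
        shifted = guided_filter(p + c, guide, 1, 0.05)
        np.testing.assert_allclose(shifted, base + c, atol=1e-9)

    def test_rejects_dim_mismatch(self):
        with pytest.raises(ValueError):
            guided_filter(np.zeros((5, 5)), np.zeros((6, 5)), 1, 0.1)


class TestFastGuidedFilter:
    def test_subsample_one_equals_exact(self, rng):
        p = rng.uniform(0.0, 1.0, (16, 16))
        guide = rng.uniform(0.0, 1.0, (16, 16))
        exact = guided_filter(p, guide, 3, 0.04)
        fast = fast_guided_filter(p, guide, GuidedFilterParams(3, 0.04, 1))
        np.testing.assert_allclose(fast, exact, atol=1e-12)

    def test_constant_inputs_pass_through(self):
        p = np.full((32, 32), 0.3)
        out = fast_guided_filter(p, np.full((32, 32), 0.7), GuidedFilterParams(4, 0.1, 4))
        np.testing.assert_allclose(out, 0.3, atol=1e-12)

    def test_close_to_exact_on_smooth_images(self, rng):
        p = gaussian_lowpass(rng.uniform(0.0, 1.0, (64, 64)), 11, 3.0)
        guide = gaussian_lowpass(rng.uniform(0.0, 1.0, (64, 64)), 11, 3.0)
        exact = guided_filter(p, guide, 8, 0.01)
        fast = fast_guided_filter(p, guide, GuidedFilterParams(8, 0.01, 4))
        assert np.max(np.abs(fast - exact)) < 0.05

    def test_rejects_degenerate_subsample(self):
        with pytest.raises(ValueError):
            fast_guided_filter(
                np.zeros((16, 16)), np.zeros((16, 16)), GuidedFilterParams(2, 0.1, 5)
            )

    @pytest.mark.parametrize("s", [1, 2, 4])
    def test_output_finite_and_shape_preserved(self, rng, s):
        p = rng.uniform(0.0, 1.0, (32, 24))
        guide = rng.uniform(0.0, 1.0, (32, 24))
        out = fast_guided_filter(p, guide, GuidedFilterParams(4, 0.05, s))
        assert out.shape == p.shape
        assert np.all(np.isfinite(out))
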