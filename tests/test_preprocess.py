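"""Convolution and Sobel gradient-magnitude tests.

The reference here is a brute-force direct-summation convolution written
independently of the implementation: for every output pixel it sums
f(k1, k2)·g(k1−n1, k2−n2) over the kernel support with zero extension
outside the frame.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from acqua.errors import ValidationError
from acqua.preprocess import (SOBEL_H, SOBEL_V, as_gray, convolve2d,
                              normalize_gradient, sobel_magnitude)


def brute_force_convolve(image, kernel):
    """Direct double-loop true convolution, zero-padded, same-size output."""
    f = np.asarray(image, dtype=float)
    g = np.asarray(kernel, dtype=float)
    kh, kw = g.shape
    ch, cw = kh // 2, kw // 2
    out = np.zeros_like(f)
    for n1 in range(f.shape[0]):
        for n2 in range(f.shape[1]):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    k1 = n1 - (a - ch)
                    k2 = n2 - (b - cw)
                    if 0 <= k1 < f.shape[0] and 0 <= k2 < f.shape[1]:
                        acc += f[k1, k2] * g[a, b]
            out[n1, n2] = acc
    return out


class TestConvolve2d:
    def test_constant_image_with_sobel_v_is_zero_in_interior(self):
        img = np.full((5, 5), 7.0)
        out = convolve2d(img, SOBEL_V)
        assert np.allclose(out[1:-1, 1:-1], 0.0)

    def test_impulse_response_identity(self, rng):
        # delta * g = g under true convolution; correlation would stamp the
        # index-reversed kernel instead
        kernel = rng.normal(size=(3, 3))
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        out = convolve2d(img, kernel)
        assert np.allclose(out[1:4, 1:4], kernel)

    @pytest.mark.parametrize("kernel", [SOBEL_V, SOBEL_H], ids=["g_v", "g_h"])
    def test_matches_brute_force_on_random_image(self, kernel, rng):
        img = rng.normal(size=(16, 16))
        assert np.allclose(convolve2d(img, kernel), brute_force_convolve(img, kernel),
                           atol=1e-10)

    def test_linearity(self, rng):
        a, b = 2.5, -1.25
        i1, i2 = rng.normal(size=(12, 12)), rng.normal(size=(12, 12))
        lhs = convolve2d(a * i1 + b * i2, SOBEL_V)
        rhs = a * convolve2d(i1, SOBEL_V) + b * convolve2d(i2, SOBEL_V)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_rejects_non_finite_pixels(self):
        img = np.ones((5, 5))
        img[2, 2] = np.nan
        with pytest.raises(ValidationError):
            convolve2d(img, SOBEL_V)

    def test_rejects_kernel_larger_than_image(self):
        with pytest.raises(ValidationError):
            convolve2d(np.ones((2, 2)), SOBEL_V)


class TestSobelMagnitude:
    def test_kernels_as_printed(self):
        assert SOBEL_V.tolist() == [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]
        assert SOBEL_H.tolist() == [[1, 2, 1], [0, 0, 0], [-1, -2, -1]]
        assert np.allclose(SOBEL_V.sum(axis=1), 0)  # rows of g_v
        assert np.allclose(SOBEL_H.sum(axis=0), 0)  # columns of g_h

    def test_constant_image_has_zero_interior_gradient(self):
        H = sobel_magnitude(np.full((8, 8), 3.3))["H"]
        assert np.allclose(H[1:-1, 1:-1], 0.0)

    def test_horizontal_ramp_gives_H_eight_times_step(self):
        # f(k1, k2) = k2: the 3x3 stencil sums to 8 per unit step
        img = np.tile(np.arange(10, dtype=float), (10, 1))
        g = sobel_magnitude(img)
        assert np.allclose(np.abs(g["h_v"][1:-1, 1:-1]), 8.0)
        assert np.allclose(g["h_h"][1:-1, 1:-1], 0.0)
        assert np.allclose(g["H"][1:-1, 1:-1], 8.0)

    def test_matches_brute_force_composition(self, rng):
        img = rng.normal(size=(14, 14))
        H = sobel_magnitude(img)["H"]
        expected = np.sqrt(brute_force_convolve(img, SOBEL_V) ** 2
                           + brute_force_convolve(img, SOBEL_H) ** 2)
        assert np.allclose(H, expected, atol=1e-9)

    def test_H_invariant_to_kernel_sign(self, rng):
        img = rng.normal(size=(10, 10))
        H = sobel_magnitude(img)["H"]
        hv = convolve2d(img, -SOBEL_V)
        hh = convolve2d(img, -SOBEL_H)
        assert np.allclose(H, np.hypot(hv, hh), atol=1e-12)

    def test_rotation_symmetry(self, rng):
        # g_h is the transpose-reversal of g_v, so H commutes with 90° rotation
        img = rng.normal(size=(12, 12))
        H = sobel_magnitude(img)["H"]
        H_rot = np.rot90(sobel_magnitude(np.rot90(img))["H"], k=-1)
        assert np.allclose(H[1:-1, 1:-1], H_rot[1:-1, 1:-1], atol=1e-9)

    def test_rejects_tiny_image(self):
        with pytest.raises(ValidationError):
            sobel_magnitude(np.ones((2, 5)))


class TestNormalizeGradient:
    def test_linear_map(self):
        H = np.array([[2.0, 6.0], [10.0, 2.0]])
        out = normalize_gradient(H)
        assert out[0, 1] == pytest.approx(0.5)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_all_zero_input_maps_to_zero(self):
        assert not normalize_gradient(np.zeros((4, 4))).any()

    def test_range_contract(self, rng):
        out = normalize_gradient(rng.uniform(3, 9, size=(6, 6)))
        assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(1.0)


class TestAsGray:
    def test_rgb_uses_fixed_luminance_weights(self):
        rgb = np.zeros((2, 2, 3))
        rgb[..., 1] = 1.0
        assert np.allclose(as_gray(rgb), 0.587)

    def test_uint8_rescaled_to_unit_interval(self):
        arr = np.array([[0, 255]], dtype=np.uint8)
        assert np.allclose(as_gray(arr), [[0.0, 1.0]])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(hnp.arrays(np.float64, hnp.array_shapes(min_dims=2, max_dims=2, min_side=3, max_side=12),
                  elements=st.floats(-100, 100)))
def test_convolution_matches_oracle_property(img):
    """Any finite image: implementation equals the direct-summation oracle."""
    for kernel in (SOBEL_V, SOBEL_H):
        assert np.allclose(convolve2d(img, kernel), brute_force_convolve(img, kernel),
                           atol=1e-7)
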