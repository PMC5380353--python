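"""Region means, bias-field estimation, fitted images and SPF forces,
checked against independent direct-summation oracles."""

import numpy as np
import pytest

from lgfiseg.core import KernelSpec, characteristic_2p, characteristic_4p
from lgfiseg.fitting import (
    bias_field,
    fitted_images_2p,
    fitted_images_4p,
    global_means,
    gspf,
    local_means,
    lspf,
)

EPS = 1.5


def naive_convolve(a: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Direct 2-D correlation with the truncated unit-sum Gaussian and
    edge-symmetric padding; the independent oracle for all convolutions."""
    r = kernel.truncation_radius
    k2 = kernel.kernel_2d()
    padded = np.pad(np.asarray(a, dtype=float), r, mode="symmetric")
    out = np.zeros_like(np.asarray(a, dtype=float))
    h, w = out.shape
    for i in range(h):
        for j in range(w):
            out[i, j] = np.sum(padded[i : i + 2 * r + 1, j : j + 2 * r + 1] * k2)
    return out


def naive_local_means(image, bias, M, kernel):
    num = naive_convolve(bias, kernel) * image
    den = naive_convolve(bias * bias, kernel)
    return [float(np.sum(num * Mi) / np.sum(den * Mi)) for Mi in M]


def naive_bias(image, local, M, kernel):
    num = sum(naive_convolve(image * ci * Mi, kernel)
              for ci, Mi in zip(local, M))
    den = sum(naive_convolve(ci * ci * Mi, kernel)
              for ci, Mi in zip(local, M))
    return num / den


class TestGlobalMeans:
    def test_two_value_strip(self):
        image = np.array([[10.0, 10.0, 20.0, 20.0]])
        beta = 1e9
        phi = np.array([[beta, beta, -beta, -beta]])
        m = global_means(image, characteristic_2p(phi, EPS))
        assert m[0] == pytest.approx(10.0, abs=1e-6)
        assert m[1] == pytest.approx(20.0, abs=1e-6)

    def test_constant_image(self):
        image = np.full((6, 6), 42.0)
        m = global_means(image, characteristic_2p(np.ones((6, 6)), EPS))
        assert m == pytest.approx([42.0, 42.0])

    def test_zero_levelset_gives_overall_mean(self, rng):
        image = rng.uniform(0, 255, (8, 8))
        m = global_means(image, characteristic_2p(np.zeros((8, 8)), EPS))
        assert m[0] == pytest.approx(image.mean())
        assert m[1] == pytest.approx(image.mean())

    def test_degenerate_phase_falls_back_to_image_mean(self, rng):
        image = rng.uniform(0, 255, (5, 5))
        M = (np.ones_like(image), np.zeros_like(image))
        with pytest.warns(UserWarning):
            m = global_means(image, M)
        assert m[1] == pytest.approx(image.mean())

    def test_means_within_image_range(self, rng):
        image = rng.uniform(10, 200, (10, 10))
        phi = rng.normal(size=(10, 10))
        for mi in global_means(image, characteristic_2p(phi, EPS)):
            assert image.min() <= mi <= image.max()


class TestLocalMeans:
    def test_constant_image_unit_bias(self):
        image = np.full((8, 8), 9.0)
        M = characteristic_2p(np.ones((8, 8)), EPS)
        c = local_means(image, np.ones_like(image), M, KernelSpec(1.0))
        assert c == pytest.approx([9.0, 9.0])

    def test_wide_kernel_recovers_global_means(self, rng):
        image = rng.uniform(0, 255, (12, 12))
        phi = rng.normal(size=(12, 12))
        M = characteristic_2p(phi, EPS)
        m = global_means(image, M)
        # kernel much wider than the image: local averaging spans everything
        c = local_means(image, np.ones_like(image), M, KernelSpec(200.0))
        assert c == pytest.approx(m, abs=1e-3)

    def test_matches_direct_summation_oracle(self, rng):
        image = rng.uniform(0, 255, (8, 8))
        bias = rng.uniform(0.5, 1.5, (8, 8))
        M = characteristic_2p(rng.normal(size=(8, 8)), EPS)
        kernel = KernelSpec(1.0)
        c = local_means(image, bias, M, kernel)
        expected = naive_local_means(image, bias, M, kernel)
        assert c == pytest.approx(expected, abs=1e-10)

    def test_degenerate_bias_falls_back(self, rng):
        image = rng.uniform(0, 255, (6, 6))
        M = characteristic_2p(rng.normal(size=(6, 6)), EPS)
        c = local_means(image, np.zeros_like(image), M, KernelSpec(1.0),
                        fallback=[11.0, 22.0])
        assert c == [11.0, 22.0]


class TestBiasField:
    def test_constant_image_gives_unit_bias(self):
        image = np.full((10, 10), 50.0)
        M = characteristic_2p(np.zeros((10, 10)), EPS)
        b = bias_field(image, [50.0, 50.0], M, KernelSpec(1.5))
        assert b == pytest.approx(np.ones_like(image))

    def test_matches_direct_summation_oracle(self, rng):
        image = rng.uniform(0, 255, (8, 8))
        M = characteristic_2p(rng.normal(size=(8, 8)), EPS)
        local = [80.0, 170.0]
        kernel = KernelSpec(1.0)
        b = bias_field(image, local, M, kernel)
        expected = naive_bias(image, local, M, kernel)
        assert b == pytest.approx(expected, abs=1e-10)

    def test_positive_floor(self):
        image = np.zeros((6, 6))
        M = characteristic_2p(np.zeros((6, 6)), EPS)
        b = bias_field(image, [5.0, 5.0], M, KernelSpec(1.0))
        assert np.all(b >= 1e-3)

    def test_all_zero_means_gives_unit_bias(self, rng):
        image = rng.uniform(0, 255, (5, 5))
        M = characteristic_2p(np.zeros((5, 5)), EPS)
        with pytest.warns(UserWarning):
            b = bias_field(image, [0.0, 0.0], M, KernelSpec(1.0))
        assert b == pytest.approx(np.ones_like(image))


class TestOracleEquivalenceFourPhase:
    def test_four_phase_means_and_bias(self, rng):
        image = rng.uniform(0, 255, (12, 12))
        bias = rng.uniform(0.8, 1.2, (12, 12))
        M = characteristic_4p(rng.normal(size=(12, 12)),
                              rng.normal(size=(12, 12)), EPS)
        kernel = KernelSpec(1.0)
        c = local_means(image, bias, M, kernel)
        assert c == pytest.approx(naive_local_means(image, bias, M, kernel),
                                  abs=1e-10)
        b = bias_field(image, c, M, kernel)
        assert b == pytest.approx(naive_bias(image, c, M, kernel), abs=1e-10)


class TestFittedImages:
    def test_partition_collapse_two_phase(self, rng):
        M = characteristic_2p(rng.normal(size=(7, 7)), EPS)
        fit = fitted_images_2p(np.ones((7, 7)), [5.0, 5.0], [9.0, 9.0], M)
        assert fit.bias_local == pytest.approx(np.full((7, 7), 5.0))
        assert fit.global_ == pytest.approx(np.full((7, 7), 9.0))

    def test_partition_collapse_four_phase(self, rng):
        M = characteristic_4p(rng.normal(size=(7, 7)),
                              rng.normal(size=(7, 7)), EPS)
        fit = fitted_images_4p(np.ones((7, 7)), [3.0] * 4, [8.0] * 4, M)
        assert fit.bias_local == pytest.approx(np.full((7, 7), 3.0))
        assert fit.global_ == pytest.approx(np.full((7, 7), 8.0))

    def test_convex_bounds(self, rng):
        M = characteristic_2p(rng.normal(size=(9, 9)), EPS)
        bias = rng.uniform(0.5, 2.0, (9, 9))
        c = [40.0, 90.0]
        fit = fitted_images_2p(bias, c, [1.0, 2.0], M)
        assert np.all(fit.bias_local >= min(c) * bias.min() - 1e-9)
        assert np.all(fit.bias_local <= max(c) * bias.max() + 1e-9)

    def test_phase_count_validation(self):
        M2 = characteristic_2p(np.zeros((3, 3)), EPS)
        with pytest.raises(ValueError):
            fitted_images_4p(np.ones((3, 3)), [1, 2], [1, 2], M2)


class TestSPF:
    @staticmethod
    def _fit(image, rng):
        M = characteristic_2p(rng.normal(size=image.shape), EPS)
        c = local_means(image, np.ones_like(image), M, KernelSpec(1.5))
        m = global_means(image, M)
        return fitted_images_2p(np.ones_like(image), c, m, M)

    def test_range_bounded(self, rng):
        image = rng.uniform(0, 255, (15, 15))
        fit = self._fit(image, rng)
        for spf in (lspf(image, fit), gspf(image, fit)):
            assert np.all(spf.values >= -1) and np.all(spf.values <= 1)
            assert not spf.vanished

    def test_zero_intensity_branch(self, rng):
        image = rng.uniform(50, 255, (10, 10))
        image[2:4, 2:4] = 0.0
        fit = self._fit(image, rng)
        assert np.all(lspf(image, fit).values[2:4, 2:4] == 0)
        assert np.all(gspf(image, fit).values[2:4, 2:4] == 0)

    def test_vanished_residual_flag(self):
        image = np.full((6, 6), 20.0)
        M = characteristic_2p(np.zeros((6, 6)), EPS)
        fit = fitted_images_2p(np.ones((6, 6)), [20.0, 20.0], [20.0, 20.0], M)
        out = lspf(image, fit)
        assert out.vanished
        assert out.values == pytest.approx(np.zeros((6, 6)))

    def test_extreme_pixel_reaches_unit(self, rng):
        image = np.full((8, 8), 100.0)
        image[4, 4] = 250.0
        fit = fitted_images_2p(
            np.ones((8, 8)), [100.0, 100.0], [100.0, 100.0],
            characteristic_2p(np.zeros((8, 8)), EPS))
        assert abs(gspf(image, fit).values[4, 4]) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        image = rng.uniform(1, 255, (12, 12))
        phi = rng.normal(size=(12, 12))
        M = characteristic_2p(phi, EPS)

        def spfs(img):
            m = global_means(img, M)
            c = local_means(img, np.ones_like(img), M, KernelSpec(1.5))
            fit = fitted_images_2p(np.ones_like(img), c, m, M)
            return lspf(img, fit).values, gspf(img, fit).values

        l1, g1 = spfs(image)
        l2, g2 = spfs(3.7 * image)
        np.testing.assert_allclose(l1, l2, atol=1e-12)
        np.testing.assert_allclose(g1, g2, atol=1e-12)

    def test_scale_equivariance_of_means(self, rng):
        image = rng.uniform(1, 100, (10, 10))
        M = characteristic_2p(rng.normal(size=(10, 10)), EPS)
        k = 2.5
        m1 = global_means(image, M)
        m2 = global_means(k * image, M)
        assert m2 == pytest.approx([k * v for v in m1])
        c1 = local_means(image, np.ones_like(image), M, KernelSpec(1.5))
        c2 = local_means(k * image, np.ones_like(image), M, KernelSpec(1.5))
        assert c2 == pytest.approx([k * v for v in c1])
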