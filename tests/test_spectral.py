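"""Radial spectra, slope protocols, Fourier sigma, and fractal dimensions."""

import numpy as np
import pytest

from qipbox.balance import DegenerateImageWarning
from qipbox.io import GrayImage, RasterImage
from qipbox.spectral import (
    _ols,
    fourier_sigma,
    fourier_slope,
    fractal_dim_2d,
    fractal_dim_3d,
    radial_spectrum,
)
from qipbox.synthetic import fbm_surface, random_phase_image


def power_law_image(size, alpha, exact_annuli=True):
    """Image whose radial amplitude is an exact power law of the ROUNDED
    radius, so annulus means are exactly on the line (zero-residual limit)."""
    f = np.fft.fftfreq(size) * size
    r = np.hypot(f[:, None], f[None, :])
    if exact_annuli:
        r = np.round(r)
    with np.errstate(divide="ignore"):
        amp = np.where(r > 0, r ** (-alpha), 0.0)
    rng = np.random.default_rng(0)
    w = np.fft.fft2(rng.standard_normal((size, size)))
    mag = np.abs(w)
    mag[mag == 0] = 1
    img = np.fft.ifft2(amp * w / mag).real
    img = (img - img.min()) / np.ptp(img) * 255
    return GrayImage(img)


class TestRadialSpectrum:
    def test_requires_square(self):
        with pytest.raises(ValueError, match="square"):
            radial_spectrum(GrayImage(np.zeros((8, 16))))

    def test_unit_impulse_flat_spectrum(self):
        g = np.zeros((64, 64))
        g[0, 0] = 255.0
        spec = radial_spectrum(GrayImage(g), "amplitude")
        np.testing.assert_allclose(spec.value, spec.value[0], rtol=1e-9)

    def test_white_noise_slope_near_zero(self, rng):
        g = GrayImage(rng.uniform(0, 255, (512, 512)))
        spec = radial_spectrum(g, "amplitude")
        slope, _ = _ols(np.log10(spec.frequency), np.log10(spec.value))
        assert abs(slope) < 0.05

    def test_constructed_inverse_law_recovered(self):
        g = random_phase_image(1024, 1.0, seed=1)
        spec = radial_spectrum(g, "amplitude")
        slope, _ = _ols(np.log10(spec.frequency), np.log10(spec.value))
        assert slope == pytest.approx(-1.0, abs=0.05)


class TestFourierSlope:
    def test_methods_recover_construction_at_1024(self):
        g = random_phase_image(1024, 1.0, seed=2)
        assert fourier_slope(g, "spehar").slope == pytest.approx(-1.0, abs=0.1)
        assert fourier_slope(g, "mather").slope == pytest.approx(-1.0, abs=0.1)
        # redies fits the POWER spectrum: twice the amplitude slope
        assert fourier_slope(g, "redies").slope == pytest.approx(-2.0, abs=0.1)

    def test_white_noise_flat(self, rng):
        g = GrayImage(rng.uniform(0, 255, (1024, 1024)))
        assert abs(fourier_slope(g, "spehar").slope) < 0.05
        assert abs(fourier_slope(g, "mather").slope) < 0.05
        assert abs(fourier_slope(g, "redies").slope) < 0.05

    def test_power_equals_twice_amplitude_same_protocol(self):
        # exact identity when the amplitude is constant within each annulus
        # (mean of squares equals square of mean)
        g = power_law_image(256, 1.2, exact_annuli=True)
        amp = radial_spectrum(g, "amplitude")
        pw = radial_spectrum(g, "power")
        sa, _ = _ols(np.log10(amp.frequency), np.log10(amp.value))
        sp, _ = _ols(np.log10(pw.frequency), np.log10(pw.value))
        assert sp == pytest.approx(2 * sa, abs=1e-6)

    def test_intensity_scaling_invariance(self):
        g = random_phase_image(256, 1.0, seed=4)
        half = GrayImage(g.pixels * 0.5)
        for method in ("spehar", "redies", "mather"):
            a = fourier_slope(g, method)
            b = fourier_slope(half, method)
            # mather's L* transform is nonlinear; gray methods are exact
            tol = 1e-6 if method != "mather" else 0.05
            assert a.slope == pytest.approx(b.slope, abs=tol)

    def test_degenerate_constant_nan(self):
        g = GrayImage(np.full((64, 64), 128.0))
        with pytest.warns(DegenerateImageWarning):
            fit = fourier_slope(g, "spehar")
        assert np.isnan(fit.slope)

    def test_accepts_rgb_raster(self, rp_image_256):
        fit = fourier_slope(rp_image_256, "spehar")
        assert np.isfinite(fit.slope)


class TestFourierSigma:
    def test_exact_power_law_near_zero_residual(self):
        g = power_law_image(1024, 1.0)
        assert fourier_sigma(g, binned=True) < 1e-3

    def test_nonnegative(self, rng):
        g = GrayImage(rng.uniform(0, 255, (256, 256)))
        assert fourier_sigma(g) >= 0.0
        assert fourier_sigma(g, binned=True) >= 0.0

    def test_sinusoidal_perturbation_analytic_residual(self):
        # build a spectrum log10 P = c + s*log10 f + a*sin(...); the mean
        # squared residual about the fitted line approaches a^2/2
        size = 1024
        f = np.fft.fftfreq(size) * size
        r = np.round(np.hypot(f[:, None], f[None, :]))
        a = 0.2
        with np.errstate(divide="ignore"):
            logp = np.where(r > 0, -1.5 * np.log10(np.maximum(r, 1))
                            + a * np.sin(6 * np.pi * np.log10(np.maximum(r, 1))),
                            0)
        amp = np.where(r > 0, 10 ** (logp / 2), 0.0)
        rng = np.random.default_rng(1)
        w = np.fft.fft2(rng.standard_normal((size, size)))
        mag = np.abs(w)
        mag[mag == 0] = 1
        img = np.fft.ifft2(amp * w / mag).real
        img = (img - img.min()) / np.ptp(img) * 255
        sigma = fourier_sigma(GrayImage(img), binned=False)
        assert sigma == pytest.approx(a * a / 2, rel=0.2)


class TestFractal2D:
    def test_straight_boundary_dimension_one(self):
        # axis-aligned boundary offset from all box grids
        g = np.zeros((256, 256))
        g[:, 129:] = 255.0
        fd = fractal_dim_2d(GrayImage(g))
        assert fd.D == pytest.approx(1.0, abs=0.05)

    def test_salt_and_pepper_near_two(self, rng):
        g = rng.choice([0.0, 255.0], size=(256, 256))
        fd = fractal_dim_2d(GrayImage(g))
        assert fd.D >= 1.9

    def test_counts_match_per_box_double_loop(self, rng):
        g = rng.choice([0.0, 255.0], size=(16, 16))
        fd = fractal_dim_2d(GrayImage(g))
        from qipbox.spectral import _as_lstar

        L = _as_lstar(GrayImage(g)).pixels
        black = L < L.mean()
        for box, count in zip(fd.box_sizes.astype(int), fd.counts.astype(int)):
            n = 0
            for i in range(0, 16, box):
                for j in range(0, 16, box):
                    blk = black[i:i + box, j:j + box]
                    if blk.any() and not blk.all():
                        n += 1
            assert n == count

    def test_steeper_spectrum_means_lower_dimension(self):
        ds = [fractal_dim_2d(random_phase_image(512, a, seed=5)).D
              for a in (0.6, 1.0, 1.4, 1.8)]
        assert all(x > y for x, y in zip(ds, ds[1:]))

    def test_constant_nan(self):
        with pytest.warns(DegenerateImageWarning):
            fd = fractal_dim_2d(GrayImage(np.full((64, 64), 9.0)))
        assert np.isnan(fd.D)


class TestFractal3D:
    def test_planar_ramp_dimension_two(self):
        # ramp linear in L*: every s-box range equals the box height exactly,
        # the closed-form smooth-surface limit
        y = np.linspace(0, 100, 256)
        g = GrayImage(np.tile(y, (256, 1)), scale_tag="lstar")
        fd = fractal_dim_3d(g)
        assert fd.D == pytest.approx(2.0, abs=0.1)

    def test_fbm_hurst_half(self):
        fd = fractal_dim_3d(fbm_surface(512, 0.5, seed=3))
        assert fd.D == pytest.approx(2.5, abs=0.15)

    def test_fbm_hurst_08(self):
        fd = fractal_dim_3d(fbm_surface(512, 0.8, seed=3))
        assert fd.D == pytest.approx(2.2, abs=0.15)

    def test_constant_nan(self):
        with pytest.warns(DegenerateImageWarning):
            fd = fractal_dim_3d(GrayImage(np.full((64, 64), 9.0)))
        assert np.isnan(fd.D)
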