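"""Radially averaged Fourier spectra, slope protocols, Fourier sigma, and
box-counting fractal dimensions.

Three published protocols for the log-log spectral slope are implemented
side by side; they differ in pre-processing, in whether amplitude or power
is fitted, and in which frequencies are excluded (see ``fourier_slope``).
On images with a clean power-law spectrum the three agree almost perfectly;
on natural images they diverge, which is why all three are exposed.

The 2D fractal dimension box-counts the black/white boundary of the
mean-lightness-binarized image (range 1-2); the 3D (differential) variant
box-counts the gray-level surface of the L* channel (range 2-3). For
fractional-Brownian surfaces with Hurst exponent H the 3D dimension is
3 - H, and a steeper spectral slope implies a lower dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Union

import numpy as np

from .balance import DegenerateImageWarning
from .io import (
    GrayImage,
    RasterImage,
    SizePolicy,
    convert_color,
    standardize_size,
)

__all__ = [
    "RadialSpectrum",
    "SlopeFit",
    "FractalDim",
    "radial_spectrum",
    "fourier_slope",
    "fourier_sigma",
    "fractal_dim_2d",
    "fractal_dim_3d",
]

SpectrumMode = Literal["amplitude", "power"]
SlopeMethod = Literal["spehar", "redies", "mather"]

ImageLike = Union[RasterImage, GrayImage]


def _as_gray8(img: ImageLike) -> GrayImage:
    if isinstance(img, GrayImage):
        if img.scale_tag == "lstar":
            return GrayImage(img.pixels * 2.55, scale_tag="8bit")
        return img
    return convert_color(img, "gray8")


def _as_lstar(img: ImageLike) -> GrayImage:
    """CIELAB L* plane; float gray inputs are converted without quantization."""
    from skimage.color import rgb2lab

    if isinstance(img, GrayImage):
        if img.scale_tag == "lstar":
            return img
        lab = rgb2lab(np.stack([img.pixels / 255.0] * 3, axis=-1))
        return GrayImage(np.clip(lab[..., 0], 0, 100), scale_tag="lstar")
    lab = convert_color(img, "lab")
    return GrayImage(np.clip(lab.L, 0, 100), scale_tag="lstar")

REDIES_FMIN = 10
REDIES_FMAX = 256
REDIES_NBINS = 100


@dataclass
class RadialSpectrum:
    """Radially averaged Fourier spectrum of a square image.

    ``value[i]`` is the mean amplitude (or power) over the annulus of
    rounded integer radius ``frequency[i]`` (cycles/image); DC is excluded
    and radii run to N/2.
    """

    frequency: np.ndarray
    value: np.ndarray
    mode: SpectrumMode


def radial_spectrum(img: GrayImage, mode: SpectrumMode = "amplitude") -> RadialSpectrum:
    """Radially averaged spectrum; requires a square image (crop/pad first)."""
    g = img.pixels
    h, w = g.shape
    if h != w:
        raise ValueError(
            "radial_spectrum needs a square image; apply a standardize_size "
            "crop or pad policy first"
        )
    n = h
    spec = np.abs(np.fft.fft2(g))
    if mode == "power":
        spec = spec**2
    elif mode != "amplitude":
        raise ValueError(f"unknown spectrum mode {mode!r}")
    f1d = np.fft.fftfreq(n) * n
    r = np.round(np.hypot(f1d[:, None], f1d[None, :])).astype(int)
    nmax = n // 2
    sums = np.bincount(r.ravel(), weights=spec.ravel(), minlength=nmax + 1)
    counts = np.bincount(r.ravel(), minlength=nmax + 1)
    freqs = np.arange(1, nmax + 1)
    vals = sums[1 : nmax + 1] / counts[1 : nmax + 1]
    return RadialSpectrum(frequency=freqs, value=vals, mode=mode)


@dataclass
class SlopeFit:
    """A log-log regression of the radial spectrum.

    ``sigma`` is the mean squared residual of the retained points about the
    line; ``mask`` flags which of ``log_f``/``log_v`` entered the final fit.
    """

    slope: float
    intercept: float
    sigma: float
    log_f: np.ndarray
    log_v: np.ndarray
    mask: np.ndarray
    method: str
    n_half: int = 0
    binned_log_f: Optional[np.ndarray] = None
    binned_log_v: Optional[np.ndarray] = None

    @property
    def residuals(self) -> np.ndarray:
        return self.log_v[self.mask] - (
            self.intercept + self.slope * self.log_f[self.mask]
        )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    denom = (dx**2).sum()
    slope = float((dx * (y - ym)).sum() / denom)
    return slope, float(ym - slope * xm)


def _cooks_distance(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cook's distance of every point in a simple linear regression."""
    slope, intercept = _ols(x, y)
    resid = y - (intercept + slope * x)
    m = x.size
    dx = x - x.mean()
    hat = 1.0 / m + dx**2 / (dx**2).sum()
    s2 = (resid**2).sum() / (m - 2)
    if s2 <= 0:
        return np.zeros(m)
    return (resid**2 / (2.0 * s2)) * (hat / (1.0 - hat) ** 2)


def _nonpositive_warning(method: str) -> None:
    warnings.warn(f"degenerate (constant) image: {method} slope undefined",
                  DegenerateImageWarning, stacklevel=3)


def fourier_slope(
    img: ImageLike,
    method: SlopeMethod = "redies",
    cooks_threshold: Optional[float] = None,
) -> SlopeFit:
    """Fit one of the three published Fourier-slope protocols.

    spehar: 8-bit gray; center crop to the largest power-of-two square
        (skipped for already-square images); amplitude spectrum; OLS over
        all radii, then one pruning pass removing points with Cook's
        distance above ``cooks_threshold`` (default 4/m) and one refit.
    redies: 8-bit gray; pad to square with the mean gray value and resize
        to 1024x1024; power spectrum; radii from 10 to 256 cycles/image;
        points averaged in 100 equal-width bins of log10 frequency before
        the fit.
    mather: CIELAB L* channel; center crop to the largest power-of-two
        square and resize to 1024x1024; amplitude spectrum; the lowest and
        highest quartiles of the available radii are dropped and the middle
        half is fitted.
    """
    if method == "spehar":
        gray = _as_gray8(img)
        if gray.height != gray.width:
            gray = standardize_size(gray, SizePolicy("center_crop_square_pow2"))
        spec = radial_spectrum(gray, "amplitude")
        return _fit_spehar(spec, cooks_threshold)
    if method == "redies":
        gray = _as_gray8(img)
        gray = standardize_size(gray, SizePolicy("pad_square_mean_gray"))
        gray = standardize_size(gray, SizePolicy("fixed_square", 1024))
        spec = radial_spectrum(gray, "power")
        return _fit_redies(spec)
    if method == "mather":
        limg = _as_lstar(img)
        limg = standardize_size(limg, SizePolicy("center_crop_square_pow2"))
        limg = standardize_size(limg, SizePolicy("fixed_square", 1024))
        spec = radial_spectrum(limg, "amplitude")
        return _fit_mather(spec)
    raise ValueError(f"unknown slope method {method!r}")


def _prepare_loglog(spec: RadialSpectrum) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pos = spec.value > 0
    return np.log10(spec.frequency[pos]), np.log10(spec.value[pos]), pos


def _nan_fit(spec: RadialSpectrum, method: str) -> SlopeFit:
    _nonpositive_warning(method)
    return SlopeFit(
        slope=float("nan"), intercept=float("nan"), sigma=float("nan"),
        log_f=np.array([]), log_v=np.array([]), mask=np.array([], dtype=bool),
        method=method, n_half=int(spec.frequency[-1]) if spec.frequency.size else 0,
    )


def _fit_spehar(spec: RadialSpectrum, cooks_threshold: Optional[float]) -> SlopeFit:
    if not (spec.value > 0).any():
        return _nan_fit(spec, "spehar")
    lf, lv, _ = _prepare_loglog(spec)
    thresh = cooks_threshold if cooks_threshold is not None else 4.0 / lf.size
    keep = _cooks_distance(lf, lv) <= thresh
    if keep.sum() < 2:
        keep = np.ones(lf.size, dtype=bool)
    slope, intercept = _ols(lf[keep], lv[keep])
    resid = lv[keep] - (intercept + slope * lf[keep])
    return SlopeFit(
        slope=slope, intercept=intercept, sigma=float((resid**2).mean()),
        log_f=lf, log_v=lv, mask=keep, method="spehar",
        n_half=int(spec.frequency[-1]),
    )


def _fit_redies(spec: RadialSpectrum) -> SlopeFit:
    band = (spec.frequency >= REDIES_FMIN) & (spec.frequency <= REDIES_FMAX)
    vals = spec.value[band]
    if not (vals > 0).any():
        return _nan_fit(spec, "redies")
    pos = vals > 0
    lf = np.log10(spec.frequency[band][pos])
    lv = np.log10(vals[pos])
    edges = np.linspace(np.log10(REDIES_FMIN), np.log10(REDIES_FMAX),
                        REDIES_NBINS + 1)
    idx = np.clip(np.digitize(lf, edges) - 1, 0, REDIES_NBINS - 1)
    counts = np.bincount(idx, minlength=REDIES_NBINS)
    filled = counts > 0
    bf = np.bincount(idx, weights=lf, minlength=REDIES_NBINS)[filled] / counts[filled]
    bv = np.bincount(idx, weights=lv, minlength=REDIES_NBINS)[filled] / counts[filled]
    slope, intercept = _ols(bf, bv)
    resid = bv - (intercept + slope * bf)
    return SlopeFit(
        slope=slope, intercept=intercept, sigma=float((resid**2).mean()),
        log_f=lf, log_v=lv, mask=np.ones(lf.size, dtype=bool), method="redies",
        n_half=int(spec.frequency[-1]), binned_log_f=bf, binned_log_v=bv,
    )


def _fit_mather(spec: RadialSpectrum) -> SlopeFit:
    n_radii = spec.frequency.size
    lo = n_radii // 4
    hi = n_radii - n_radii // 4
    band = np.zeros(n_radii, dtype=bool)
    band[lo:hi] = True
    vals = spec.value[band]
    if not (vals > 0).any():
        return _nan_fit(spec, "mather")
    pos = vals > 0
    lf = np.log10(spec.frequency[band][pos])
    lv = np.log10(vals[pos])
    slope, intercept = _ols(lf, lv)
    resid = lv - (intercept + slope * lf)
    return SlopeFit(
        slope=slope, intercept=intercept, sigma=float((resid**2).mean()),
        log_f=lf, log_v=lv, mask=np.ones(lf.size, dtype=bool), method="mather",
        n_half=int(spec.frequency[-1]),
    )


def fourier_sigma(img: ImageLike, binned: bool = False) -> float:
    """Mean squared deviation of the log-log power spectrum about the fitted
    line (10-256 cycles/image, power spectrum, 1024x1024 pre-processing).

    With ``binned=False`` (the classic definition) the residuals of all raw
    radius points are used, which over-weights high frequencies; with
    ``binned=True`` the residuals of the log-binned points are used, i.e.
    the same points the line itself is fitted on.
    """
    fit = fourier_slope(img, "redies")
    if not np.isfinite(fit.slope):
        return float("nan")
    if binned:
        resid = fit.binned_log_v - (fit.intercept + fit.slope * fit.binned_log_f)
    else:
        resid = fit.log_v - (fit.intercept + fit.slope * fit.log_f)
    return float((resid**2).mean())


@dataclass
class FractalDim:
    """Box-counting fractal dimension with its log-log fit diagnostics."""

    D: float
    kind: Literal["2D", "3D"]
    box_sizes: np.ndarray = field(default_factory=lambda: np.array([]))
    counts: np.ndarray = field(default_factory=lambda: np.array([]))
    in_range: bool = True


def _pow2_box_sizes(side: int) -> list[int]:
    sizes = []
    s = side // 2
    while s >= 4:
        sizes.append(s)
        s //= 2
    return sizes


def _crop_pow2_square_L(img: ImageLike) -> np.ndarray:
    limg = standardize_size(_as_lstar(img), SizePolicy("center_crop_square_pow2"))
    return limg.pixels


def fractal_dim_2d(img: ImageLike) -> FractalDim:
    """2D box-counting dimension of the binarized boundary (range 1-2).

    The image is center-cropped to the largest power-of-two square,
    binarized at its mean L* (black strictly below), and covered with grids
    of box side L = side/2 ... 4; a box counts if it contains both black
    and white pixels. D is the OLS slope of log2 N versus log2(1/L).
    """
    L = _crop_pow2_square_L(img)
    if np.ptp(L) == 0:
        warnings.warn("constant image: 2D fractal dimension undefined",
                      DegenerateImageWarning, stacklevel=2)
        return FractalDim(float("nan"), "2D", in_range=False)
    black = L < L.mean()
    if not black.any() or black.all():
        warnings.warn("binarization produced a single class: 2D fractal "
                      "dimension undefined", DegenerateImageWarning, stacklevel=2)
        return FractalDim(float("nan"), "2D", in_range=False)
    side = L.shape[0]
    sizes, counts = [], []
    for box in _pow2_box_sizes(side):
        nb = side // box
        blocks = black.reshape(nb, box, nb, box)
        has_black = blocks.any(axis=(1, 3))
        has_white = ~blocks.all(axis=(1, 3))
        n = int((has_black & has_white).sum())
        if n > 0:
            sizes.append(box)
            counts.append(n)
    if len(sizes) < 2:
        warnings.warn("too few non-empty box scales for a 2D fit",
                      DegenerateImageWarning, stacklevel=2)
        return FractalDim(float("nan"), "2D", in_range=False)
    sizes_a = np.array(sizes, dtype=float)
    counts_a = np.array(counts, dtype=float)
    slope, _ = _ols(np.log2(1.0 / sizes_a), np.log2(counts_a))
    return FractalDim(
        D=float(slope), kind="2D", box_sizes=sizes_a, counts=counts_a,
        in_range=bool(1.0 <= slope <= 2.0),
    )


def fractal_dim_3d(img: ImageLike) -> FractalDim:
    """3D differential box-counting dimension of the L* surface (range 2-3).

    The image is cropped to the largest central power-of-two square and its
    L* channel rescaled to 0-255. For box size s, the image is partitioned
    into s x s columns; each contributes floor((max - min)/h) + 1 boxes with
    box height h = s * 255 / side. D is the OLS slope of ln N(s) versus
    ln(1/s).
    """
    L = _crop_pow2_square_L(img)
    if np.ptp(L) == 0:
        warnings.warn("constant image: 3D fractal dimension undefined",
                      DegenerateImageWarning, stacklevel=2)
        return FractalDim(float("nan"), "3D", in_range=False)
    surf = L * 2.55  # L* 0-100 -> 8-bit scale
    side = surf.shape[0]
    value_range = 255.0
    sizes, counts = [], []
    for s in _pow2_box_sizes(side):
        nb = side // s
        h_box = s * value_range / side
        blocks = surf.reshape(nb, s, nb, s)
        rng = blocks.max(axis=(1, 3)) - blocks.min(axis=(1, 3))
        n = int((np.floor(rng / h_box) + 1).sum())
        sizes.append(s)
        counts.append(n)
    sizes_a = np.array(sizes, dtype=float)
    counts_a = np.array(counts, dtype=float)
    slope, _ = _ols(np.log(1.0 / sizes_a), np.log(counts_a))
    return FractalDim(
        D=float(slope), kind="3D", box_sizes=sizes_a, counts=counts_a,
        in_range=bool(2.0 <= slope <= 3.0),
    )
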