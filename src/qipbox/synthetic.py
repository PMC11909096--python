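"""Deterministic synthetic image generators with known ground truth.

Every generator is a pure function of its parameters and seed: the random
stream is derived from the seed plus a per-generator tag, so adding or
reordering fixture calls never shifts the output of existing ones.

The generators cover the structures the measures are designed to detect:
random-phase images with a prescribed radial amplitude-spectrum exponent,
fractional-Brownian-motion surfaces with a prescribed Hurst exponent,
line-segment patterns with controlled orientation statistics and spatial
layout, exactly mirror-symmetric composites, tiled textures, and degenerate
cases (constant images, step edges, gratings).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import numpy as np

from .io import GrayImage, RasterImage

__all__ = [
    "random_phase_image",
    "fbm_surface",
    "line_pattern",
    "LinePattern",
    "mirrored_composite",
    "tiled_texture",
    "step_edge",
    "grating",
    "constant_image",
    "gray_to_raster",
]


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, generator tag)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(tag.encode()),))
    )


def _rescale_8bit(arr: np.ndarray) -> np.ndarray:
    lo, hi = arr.min(), arr.max()
    if hi <= lo:
        return np.full_like(arr, 127.5)
    return (arr - lo) / (hi - lo) * 255.0


def _radial_frequency_grid(size: int) -> np.ndarray:
    f = np.fft.fftfreq(size) * size
    return np.hypot(f[:, None], f[None, :])


def _spectral_synthesis(size: int, amp_exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Real field whose Fourier amplitude is exactly r**(-amp_exponent).

    Uniform random phases come from the FFT of white noise normalized to
    unit magnitude (Hermitian symmetry is preserved, so the inverse
    transform is real to machine precision).
    """
    noise = rng.standard_normal((size, size))
    w = np.fft.fft2(noise)
    mag = np.abs(w)
    mag[mag == 0] = 1.0
    unit = w / mag
    r = _radial_frequency_grid(size)
    with np.errstate(divide="ignore"):
        amp = np.where(r > 0, r ** (-amp_exponent), 0.0)
    field = np.fft.ifft2(amp * unit)
    assert np.abs(field.imag).max() < 1e-9 * max(np.abs(field.real).max(), 1e-300)
    return field.real


def random_phase_image(size: int, alpha: float, seed: int) -> GrayImage:
    """Random-phase image with radial amplitude spectrum proportional to
    f**(-alpha), rescaled to the 8-bit range.

    ``size`` must be a power of two. The gray values are floats in
    [0, 255]; they are not quantized to integers, so the prescribed
    power-law spectrum is preserved down to the highest frequencies.
    """
    if size < 2 or size & (size - 1):
        raise ValueError("size must be a power of two")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    field = _spectral_synthesis(size, alpha, _rng(seed, f"random_phase:{size}:{alpha}"))
    return GrayImage(_rescale_8bit(field), scale_tag="8bit")


def fbm_surface(size: int, hurst: float, seed: int) -> GrayImage:
    """Fractional-Brownian-motion gray surface with Hurst exponent H.

    Spectral synthesis with power-spectrum exponent -(2H + 2), i.e.
    amplitude exponent -(H + 1); the corresponding surface fractal
    dimension is 3 - H.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie in (0, 1)")
    field = _spectral_synthesis(
        size, hurst + 1.0, _rng(seed, f"fbm:{size}:{hurst}")
    )
    return GrayImage(_rescale_8bit(field), scale_tag="8bit")


@dataclass
class LinePattern:
    """A drawn line-segment pattern plus its exact orientation bookkeeping."""

    image: GrayImage
    orientations: np.ndarray  # degrees in [0, 180), one per segment
    centers: np.ndarray  # (n, 2) segment centers in pixel coordinates


OrientationLaw = Union[
    tuple[Literal["single"], float],
    tuple[Literal["discrete"], int],
    Literal["uniform"],
]


def line_pattern(
    size: int,
    n_segments: int,
    orientation_law: OrientationLaw = "uniform",
    layout: Literal["lattice", "random"] = "random",
    seed: int = 0,
    length: Optional[float] = None,
    thickness: float = 1.5,
    supersample: int = 4,
) -> LinePattern:
    """Anti-aliased black line segments of fixed length on a white ground.

    orientation_law: ("single", theta) draws every segment at theta
    degrees; ("discrete", k) cycles through k equally spaced orientations
    (exact counts); "uniform" draws orientations uniformly from [0, 180).
    layout "lattice" centers segments on a regular grid, "random" places
    them uniformly at random (without overlap control). Anti-aliasing is
    done by drawing at ``supersample`` x resolution and box-downsampling.
    """
    rng = _rng(seed, f"lines:{size}:{n_segments}:{orientation_law}:{layout}")
    if length is None:
        length = size / 12.0
    margin = length / 2.0 + 2.0
    if 2 * margin >= size:
        raise ValueError("segments do not fit in the image")

    if isinstance(orientation_law, tuple) and orientation_law[0] == "single":
        thetas = np.full(n_segments, float(orientation_law[1]) % 180.0)
    elif isinstance(orientation_law, tuple) and orientation_law[0] == "discrete":
        k = int(orientation_law[1])
        thetas = (np.arange(n_segments) % k) * (180.0 / k)
    elif orientation_law == "uniform":
        thetas = rng.uniform(0.0, 180.0, n_segments)
    else:
        raise ValueError(f"unknown orientation law {orientation_law!r}")

    if layout == "lattice":
        g = int(np.ceil(np.sqrt(n_segments)))
        if g * (2 * margin) > size:
            raise ValueError("lattice too dense for the segment length")
        pos1d = margin + (np.arange(g) + 0.5) * (size - 2 * margin) / g
        grid = np.array([(px, py) for py in pos1d for px in pos1d])
        centers = grid[:n_segments]
    elif layout == "random":
        centers = rng.uniform(margin, size - margin, (n_segments, 2))
    else:
        raise ValueError(f"unknown layout {layout!r}")

    ss = supersample
    canvas = np.full((size * ss, size * ss), 255.0)
    half_len = length * ss / 2.0
    half_th = thickness * ss / 2.0
    for (cx, cy), theta in zip(centers, thetas):
        _draw_segment(canvas, cx * ss, cy * ss, np.deg2rad(theta), half_len, half_th)
    down = canvas.reshape(size, ss, size, ss).mean(axis=(1, 3))
    return LinePattern(
        image=GrayImage(down, scale_tag="8bit"),
        orientations=thetas,
        centers=np.asarray(centers, dtype=np.float64),
    )


def _draw_segment(
    canvas: np.ndarray, cx: float, cy: float, theta: float,
    half_len: float, half_th: float,
) -> None:
    """Blacken pixels within half_th of the segment (local bounding box)."""
    ux, uy = np.cos(theta), np.sin(theta)
    pad = half_len + half_th + 1
    x0 = max(0, int(cx - pad))
    x1 = min(canvas.shape[1], int(cx + pad) + 1)
    y0 = max(0, int(cy - pad))
    y1 = min(canvas.shape[0], int(cy + pad) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    rx = xx + 0.5 - cx
    ry = yy + 0.5 - cy
    along = np.clip(rx * ux + ry * uy, -half_len, half_len)
    dist = np.hypot(rx - along * ux, ry - along * uy)
    canvas[y0:y1, x0:x1][dist <= half_th] = 0.0


_Image = Union[RasterImage, GrayImage]


def mirrored_composite(img: _Image, axis: Literal["lr", "ud"] = "lr") -> _Image:
    """Concatenate an image with its flip: exactly symmetric, even side."""
    px = img.pixels
    if axis == "lr":
        out = np.concatenate([px, px[:, ::-1]], axis=1)
    elif axis == "ud":
        out = np.concatenate([px, px[::-1]], axis=0)
    else:
        raise ValueError(f"unknown axis {axis!r}")
    if isinstance(img, RasterImage):
        return RasterImage(out, source_id=img.source_id)
    return GrayImage(out, scale_tag=img.scale_tag)


def tiled_texture(tile: _Image, reps: int) -> _Image:
    """Repeat a tile reps x reps times."""
    px = tile.pixels
    shape = (reps, reps) + (1,) * (px.ndim - 2)
    out = np.tile(px, shape)
    if isinstance(tile, RasterImage):
        return RasterImage(out, source_id=tile.source_id)
    return GrayImage(out, scale_tag=tile.scale_tag)


def step_edge(size: int, split: Optional[int] = None,
              low: float = 0.0, high: float = 255.0) -> GrayImage:
    """Vertical step edge: columns < split are ``low``, the rest ``high``."""
    if split is None:
        split = size // 2 + 1
    g = np.full((size, size), high)
    g[:, :split] = low
    return GrayImage(g, scale_tag="8bit")


def grating(size: int, period: float, orientation_deg: float = 0.0,
            amplitude: float = 127.0) -> GrayImage:
    """Sinusoidal grating; orientation is the direction of modulation."""
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    t = np.deg2rad(orientation_deg)
    phase = 2 * np.pi * (x * np.cos(t) + y * np.sin(t)) / period
    return GrayImage(127.5 + amplitude * np.sin(phase), scale_tag="8bit")


def constant_image(size: int, value: float = 128.0) -> GrayImage:
    return GrayImage(np.full((size, size), float(value)), scale_tag="8bit")


def gray_to_raster(img: GrayImage, source_id: str = "") -> RasterImage:
    """Promote a gray fixture to 8-bit RGB (three identical channels)."""
    g = img.pixels
    if img.scale_tag == "lstar":
        g = g * 2.55
    px = np.round(np.clip(g, 0, 255)).astype(np.uint8)
    return RasterImage(np.stack([px] * 3, axis=-1), source_id=source_id)
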