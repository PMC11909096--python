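"""First-layer convolutional-feature measures: symmetry, self-similarity,
sparseness, and variability.

All four measures read the rectified responses of a 96-filter bank of
11x11x3 kernels applied with stride 4 — the shape of the first
convolutional layer of a standard object-recognition network, whose filters
are oriented luminance edges and color-opponent blobs akin to receptive
fields in early visual cortex. Pretrained weights can be supplied as an
optional tensor asset; by default a seeded surrogate bank with the same
structure (oriented edge kernels plus center-surround color-opponent
kernels, zero-mean, unit norm) is used, which preserves every structural
property the measures rely on and keeps the package self-contained.

Input images are resized to 512x512 and trimmed by one row and column to
511x511: with kernel 11 and stride 4 this makes the 126x126 response
lattice closed under reflection, so exactly mirror-symmetric images score
exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np

from .balance import DegenerateImageWarning
from .io import RasterImage, SizePolicy, standardize_size

__all__ = [
    "FilterBankC1",
    "FeatureMapStack",
    "surrogate_bank",
    "load_pretrained_bank",
    "conv1_features",
    "cnn_symmetry",
    "cnn_self_similarity",
    "cnn_variances",
]

N_FILTERS = 96
KERNEL_SIZE = 11
STRIDE = 4
INPUT_SIDE = 511  # 512 resize minus one row/column
MAP_SIDE = (INPUT_SIDE - KERNEL_SIZE) // STRIDE + 1  # 126


@dataclass
class FilterBankC1:
    """96 kernels of shape (11, 11, 3) plus a provenance tag."""

    kernels: np.ndarray
    source: str = "surrogate"

    def __post_init__(self) -> None:
        k = np.asarray(self.kernels, dtype=np.float64)
        if k.shape != (N_FILTERS, KERNEL_SIZE, KERNEL_SIZE, 3):
            raise ValueError(
                f"bank must have shape (96, 11, 11, 3), got {k.shape}"
            )
        self.kernels = k

    def flipped(self, axis: Literal["lr", "ud", "180"]) -> "FilterBankC1":
        k = self.kernels
        if axis == "lr":
            k = k[:, :, ::-1, :]
        elif axis == "ud":
            k = k[:, ::-1, :, :]
        elif axis == "180":
            k = k[:, ::-1, ::-1, :]
        else:
            raise ValueError(f"unknown flip axis {axis!r}")
        return FilterBankC1(np.ascontiguousarray(k), source=self.source)


@dataclass
class FeatureMapStack:
    """Rectified filter responses: maps has shape (96, 126, 126)."""

    maps: np.ndarray


def surrogate_bank(seed: int = 0) -> FilterBankC1:
    """Deterministic surrogate first-layer bank.

    64 oriented luminance (Gabor-patch) kernels with random orientation,
    wavelength, and phase, plus 32 center-surround color-opponent kernels
    (red-green and blue-yellow difference-of-Gaussians). Every kernel is
    zero-mean per channel and unit L2 norm.
    """
    rng = np.random.default_rng(seed)
    half = KERNEL_SIZE // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    kernels = np.zeros((N_FILTERS, KERNEL_SIZE, KERNEL_SIZE, 3))

    for i in range(64):
        theta = rng.uniform(0, np.pi)
        lam = rng.uniform(3.5, 11.0)
        phase = rng.uniform(0, 2 * np.pi)
        sigma = rng.uniform(1.8, 3.2)
        xr = x * np.cos(theta) + y * np.sin(theta)
        yr = -x * np.sin(theta) + y * np.cos(theta)
        patch = np.exp(-(xr**2 + yr**2) / (2 * sigma**2)) * np.cos(
            2 * np.pi * xr / lam + phase
        )
        kernels[i] = patch[..., None]  # identical across channels

    for i in range(64, N_FILTERS):
        s_c = rng.uniform(1.2, 2.2)
        s_s = s_c * rng.uniform(1.6, 2.4)
        dog = np.exp(-(x**2 + y**2) / (2 * s_c**2)) - (s_c / s_s) ** 2 * np.exp(
            -(x**2 + y**2) / (2 * s_s**2)
        )
        sign = rng.choice([-1.0, 1.0])
        if rng.random() < 0.5:  # red-green opponency
            kernels[i, ..., 0] = sign * dog
            kernels[i, ..., 1] = -sign * dog
        else:  # blue-yellow opponency
            kernels[i, ..., 2] = sign * dog
            kernels[i, ..., 0] = -sign * dog / 2
            kernels[i, ..., 1] = -sign * dog / 2

    kernels -= kernels.mean(axis=(1, 2), keepdims=True)
    norms = np.sqrt((kernels**2).sum(axis=(1, 2, 3), keepdims=True))
    kernels /= np.where(norms > 0, norms, 1.0)
    return FilterBankC1(kernels, source=f"surrogate(seed={seed})")


def load_pretrained_bank(path: Union[str, Path]) -> FilterBankC1:
    """Load a pretrained first-layer weight tensor from a .npy asset.

    The file must contain a float array of shape (96, 3, 11, 11)
    (filters x channels x height x width).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"pretrained conv1 weights not found at {path}; expected a .npy "
            "tensor of shape (96, 3, 11, 11). Supply it via the "
            "--cnn-weights flag or use the default surrogate bank."
        )
    w = np.load(path)
    if w.shape != (N_FILTERS, 3, KERNEL_SIZE, KERNEL_SIZE):
        raise ValueError(
            f"expected weight shape (96, 3, 11, 11), got {w.shape}"
        )
    return FilterBankC1(np.transpose(w, (0, 2, 3, 1)), source="pretrained_asset")


def _prepare_input(img: RasterImage, bank: FilterBankC1) -> np.ndarray:
    # One symmetric bilinear resize to 511 = 512 - 1: pixel-center mapping
    # sends mirror-symmetric inputs (even or odd symmetry) to exactly
    # mirror-symmetric 511x511 arrays, and the stride-4/kernel-11 response
    # lattice on 511 is closed under reflection.
    arr = standardize_size(img, SizePolicy("fixed_square", INPUT_SIDE)).pixels
    arr = arr.astype(np.float64)
    if bank.source == "pretrained_asset":
        arr = arr - arr.mean(axis=(0, 1))  # per-channel mean (training convention)
    else:
        arr = arr - arr.mean()  # per-image mean
    return arr


def _correlate(arr: np.ndarray, bank: FilterBankC1, rectify: bool = True) -> np.ndarray:
    """Valid cross-correlation at stride 4 for all 96 kernels."""
    windows = np.lib.stride_tricks.sliding_window_view(
        arr, (KERNEL_SIZE, KERNEL_SIZE), axis=(0, 1)
    )[::STRIDE, ::STRIDE]
    # windows: (126, 126, 3, 11, 11) -> (126*126, 11*11*3) matching kernel layout
    patches = windows.transpose(0, 1, 3, 4, 2).reshape(MAP_SIDE * MAP_SIDE, -1)
    weights = bank.kernels.reshape(N_FILTERS, -1)
    resp = patches @ weights.T
    resp = resp.T.reshape(N_FILTERS, MAP_SIDE, MAP_SIDE)
    return np.maximum(resp, 0.0) if rectify else resp


def conv1_features(img: RasterImage, bank: FilterBankC1) -> FeatureMapStack:
    """Rectified stride-4 responses of the 96-filter bank (96 x 126 x 126)."""
    return FeatureMapStack(_correlate(_prepare_input(img, bank), bank))


def cnn_symmetry(
    img: RasterImage,
    bank: FilterBankC1,
    axis: Literal["lr", "ud", "lrud"] = "lr",
) -> float:
    """CNN-feature symmetry in [0, 1] via the mirrored-kernel protocol.

    The response stack R of the image is compared with the spatially
    flipped response stack of the axis-flipped kernels; the score is
    sum(min) / sum(max) over all filters and positions. For "lrud" the
    element-wise min and max run over R and all three flipped stacks.
    A mirror-symmetric image scores exactly 1.
    """
    arr = _prepare_input(img, bank)
    r = _correlate(arr, bank)
    stacks = [r]
    if axis in ("lr", "lrud"):
        stacks.append(_correlate(arr, bank.flipped("lr"))[:, :, ::-1])
    if axis in ("ud", "lrud"):
        stacks.append(_correlate(arr, bank.flipped("ud"))[:, ::-1, :])
    if axis == "lrud":
        stacks.append(_correlate(arr, bank.flipped("180"))[:, ::-1, ::-1])
    if axis not in ("lr", "ud", "lrud"):
        raise ValueError(f"unknown symmetry axis {axis!r}")
    mins = np.minimum.reduce(stacks)
    maxs = np.maximum.reduce(stacks)
    denom = maxs.sum()
    if denom <= 0:
        warnings.warn("all-zero response stack: CNN symmetry undefined",
                      DegenerateImageWarning, stacklevel=2)
        return float("nan")
    return float(mins.sum() / denom)


def _grid_bounds(extent: int, parts: int) -> np.ndarray:
    return np.round(np.arange(parts + 1) * extent / parts).astype(int)


def cnn_self_similarity(img: RasterImage, bank: FilterBankC1, grid: int = 8) -> float:
    """CNN self-similarity in [0, 1].

    The ground histogram is the 96-vector of per-filter maxima over the
    whole response map, normalized to sum 1; each of the grid x grid
    sections yields an analogous vector. The score is the median over
    sections of the histogram intersection with the ground histogram.
    """
    maps = conv1_features(img, bank).maps
    ground = maps.max(axis=(1, 2))
    gsum = ground.sum()
    if gsum <= 0:
        warnings.warn("all-zero response stack: CNN self-similarity undefined",
                      DegenerateImageWarning, stacklevel=2)
        return float("nan")
    ground = ground / gsum
    rb = _grid_bounds(maps.shape[1], grid)
    cb = _grid_bounds(maps.shape[2], grid)
    hiks = []
    for i in range(grid):
        for j in range(grid):
            sec = maps[:, rb[i]:rb[i + 1], cb[j]:cb[j + 1]].max(axis=(1, 2))
            ssum = sec.sum()
            if ssum <= 0:
                hiks.append(0.0)
                continue
            hiks.append(float(np.minimum(sec / ssum, ground).sum()))
    return float(np.median(hiks))


def pooled_grid(maps: np.ndarray, n: int = 8) -> np.ndarray:
    """Per-filter max-pooled values over an n x n partition: (96, n*n)."""
    rb = _grid_bounds(maps.shape[1], n)
    cb = _grid_bounds(maps.shape[2], n)
    out = np.empty((maps.shape[0], n * n))
    k = 0
    for i in range(n):
        for j in range(n):
            out[:, k] = maps[:, rb[i]:rb[i + 1], cb[j]:cb[j + 1]].max(axis=(1, 2))
            k += 1
    return out


def cnn_variances(
    img: RasterImage, bank: FilterBankC1, n: int = 8
) -> dict[str, float]:
    """Sparseness and Variability of max-pooled first-layer responses.

    sparseness: mean over the n*n grid cells of the variance across the 96
    filter values within each cell (low = many filters respond with similar
    strength everywhere, i.e. rich responses).
    variability: median over the 96 filters of the variance across that
    filter's n*n pooled values (low = spatially uniform responses, i.e.
    high self-similarity).
    """
    maps = conv1_features(img, bank).maps
    pooled = pooled_grid(maps, n)
    sparseness = float(pooled.var(axis=0).mean())
    variability = float(np.median(pooled.var(axis=1)))
    return {"sparseness": sparseness, "variability": variability}
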