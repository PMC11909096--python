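"""Combined L*a*b* gradient image, HOG Complexity, Anisotropy, and
PHOG-based self-similarity.

The gradient image is the per-pixel maximum of the three CIELAB channel
gradient magnitudes (lightness gradients usually dominate, but strong
isoluminant color edges still register). Orientation histograms use 16
equal bins over the full 360-degree circle, bin 0 centered at 0 degrees.
The pyramid subdivides the image into 1 / 4 / 16 / 64 equal sections at
levels 0-3; above level 3 the sections become too small and the histograms
too noisy to be meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .balance import DegenerateImageWarning
from .io import LabImage, RasterImage, SizePolicy, convert_color, standardize_size

__all__ = [
    "GradientImage",
    "HOGPyramid",
    "gradient_image",
    "complexity_hog",
    "build_phog",
    "phog_self_similarity",
    "anisotropy",
    "histogram_intersection",
    "PHOG_DEFAULT_PIXELS",
]

#: Default pre-resize target (total pixels) for the PHOG measures.
PHOG_DEFAULT_PIXELS = 100_000

N_BINS = 16
MAX_LEVEL = 3


@dataclass
class GradientImage:
    """Per-pixel gradient strength (>= 0) and orientation in [0, 360)."""

    strength: np.ndarray
    orientation: np.ndarray


def _central_diff(chan: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """[-1, 0, 1] gradients with replicated borders (canonical HOG kernel)."""
    padded = np.pad(chan, 1, mode="edge")
    gx = padded[1:-1, 2:] - padded[1:-1, :-2]
    gy = padded[2:, 1:-1] - padded[:-2, 1:-1]
    return gx, gy


def gradient_image(img: LabImage) -> GradientImage:
    """Combined gradient image over the three CIELAB channels.

    Per pixel, the strength is the largest of the three channel gradient
    magnitudes and the orientation is taken from the winning channel
    (ties resolved in L*, a*, b* order).
    """
    mags = []
    angles = []
    for chan in (img.L, img.a, img.b):
        gx, gy = _central_diff(np.asarray(chan, dtype=np.float64))
        mags.append(np.hypot(gx, gy))
        angles.append(np.degrees(np.arctan2(gy, gx)) % 360.0)
    mags = np.stack(mags)
    angles = np.stack(angles)
    winner = np.argmax(mags, axis=0)
    strength = np.take_along_axis(mags, winner[None], axis=0)[0]
    orientation = np.take_along_axis(angles, winner[None], axis=0)[0]
    return GradientImage(strength=strength, orientation=orientation)


def complexity_hog(img: RasterImage, resize_to: Optional[int] = None) -> float:
    """HOG Complexity: mean strength of the combined gradient image.

    ``resize_to`` optionally resizes the image to that total pixel count
    first (the value is size-dependent, so a fixed size aids comparability).
    """
    if resize_to is not None:
        img = standardize_size(img, SizePolicy("total_pixels", resize_to))
    grad = gradient_image(convert_color(img, "lab"))
    return float(grad.strength.mean())


@dataclass
class HOGPyramid:
    """Orientation histograms of gradient strength at pyramid levels 0..L.

    ``levels[l]`` has shape (4**l, N_BINS); section order is row-major over
    the 2**l x 2**l grid.
    """

    levels: list[np.ndarray]

    @property
    def ground(self) -> np.ndarray:
        return self.levels[0][0]


def orientation_bins(orientation: np.ndarray, bins: int = N_BINS) -> np.ndarray:
    """Bin index per pixel; equal bins over 360 deg, bin 0 centered at 0."""
    width = 360.0 / bins
    return (np.floor(((orientation + width / 2.0) % 360.0) / width)).astype(int)


def _section_bounds(extent: int, parts: int) -> np.ndarray:
    return np.round(np.arange(parts + 1) * extent / parts).astype(int)


def build_phog(
    g: GradientImage, bins: int = N_BINS, max_level: int = MAX_LEVEL
) -> HOGPyramid:
    """Pyramid of orientation histograms of summed gradient strength."""
    if max_level > MAX_LEVEL:
        raise ValueError(
            f"max_level {max_level} > {MAX_LEVEL}: histograms become unstable "
            "in exceedingly small sections"
        )
    h, w = g.strength.shape
    bin_idx = orientation_bins(g.orientation, bins)
    levels: list[np.ndarray] = []
    for lvl in range(max_level + 1):
        parts = 2**lvl
        rb = _section_bounds(h, parts)
        cb = _section_bounds(w, parts)
        hists = np.zeros((parts * parts, bins), dtype=np.float64)
        k = 0
        for i in range(parts):
            for j in range(parts):
                sl = (slice(rb[i], rb[i + 1]), slice(cb[j], cb[j + 1]))
                hists[k] = np.bincount(
                    bin_idx[sl].ravel(),
                    weights=g.strength[sl].ravel(),
                    minlength=bins,
                )
                k += 1
        levels.append(hists)
    return HOGPyramid(levels=levels)


def histogram_intersection(h1: np.ndarray, h2: np.ndarray) -> float:
    """HIK of two histograms after normalizing each to sum 1."""
    s1, s2 = h1.sum(), h2.sum()
    if s1 <= 0 or s2 <= 0:
        return float("nan")
    return float(np.minimum(h1 / s1, h2 / s2).sum())


def phog_self_similarity(
    pyr: HOGPyramid,
    levels: Sequence[int] = (1, 2, 3),
    weights: Optional[Sequence[float]] = None,
) -> float:
    """PHOG self-similarity: weighted mean over levels of the mean HIK
    between each section histogram and the ground-level histogram.

    1 means every section's orientation distribution matches the whole
    image; values near 0 mean the sections look nothing like the whole.
    """
    ground = pyr.ground
    if ground.sum() <= 0:
        warnings.warn("zero-gradient image: PHOG self-similarity undefined",
                      DegenerateImageWarning, stacklevel=2)
        return float("nan")
    if weights is None:
        weights = [1.0] * len(levels)
    if len(weights) != len(levels):
        raise ValueError("weights must match levels")
    per_level = []
    for lvl in levels:
        hists = pyr.levels[lvl]
        vals = [histogram_intersection(hsec, ground) for hsec in hists]
        per_level.append(np.nanmean(vals))
    return float(np.average(per_level, weights=weights))


def anisotropy(pyr: HOGPyramid) -> float:
    """Anisotropy: SD of the level-3 orientation distribution.

    Level-3 section histograms are summed bin-wise, normalized to sum 1,
    and the population SD of the 16 normalized bin values is returned.
    0 = perfectly isotropic gradient energy.
    """
    if len(pyr.levels) <= MAX_LEVEL:
        raise ValueError("pyramid must include level 3")
    summed = pyr.levels[MAX_LEVEL].sum(axis=0)
    total = summed.sum()
    if total <= 0:
        warnings.warn("zero-gradient image: Anisotropy undefined",
                      DegenerateImageWarning, stacklevel=2)
        return float("nan")
    return float(np.std(summed / total))


def phog_measures(
    img: RasterImage,
    resize_to: Optional[int] = PHOG_DEFAULT_PIXELS,
) -> tuple[float, float]:
    """Convenience: (self_sim_phog, anisotropy) with the standard pre-resize."""
    if resize_to is not None:
        img = standardize_size(img, SizePolicy("total_pixels", resize_to))
    pyr = build_phog(gradient_image(convert_color(img, "lab")))
    return phog_self_similarity(pyr), anisotropy(pyr)
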