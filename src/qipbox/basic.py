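"""Image dimensions, contrast, lightness entropy, and color statistics.

All measures here depend only on value histograms or moments, never on
pixel positions, so they are invariant under spatial permutation of pixels.
Entropies use 256 equal-width bins over the channel's full declared range
(L* on [0, 100], hue on [0, 1)), so the uniform-occupancy maximum is
exactly 8 bits. Standard deviations are population SDs throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io import HSVImage, LabImage, RasterImage, convert_color

__all__ = [
    "HistogramSpec",
    "ChannelStats",
    "image_size",
    "aspect_ratio",
    "rms_contrast",
    "lightness_entropy",
    "color_channel_stats",
    "color_entropy",
    "shannon_entropy",
]


@dataclass(frozen=True)
class HistogramSpec:
    """Binning for channel entropies: ``bins`` equal-width bins over ``range``."""

    bins: int = 256
    range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("need at least 2 bins")
        if not self.range[1] > self.range[0]:
            raise ValueError("empty histogram range")


#: Default binning for L* entropy and hue entropy.
LSTAR_HIST = HistogramSpec(256, (0.0, 100.0))
HUE_HIST = HistogramSpec(256, (0.0, 1.0))

CHANNEL_NAMES = ("R", "G", "B", "L", "a", "b", "H", "S", "V")


@dataclass
class ChannelStats:
    """Means and population SDs for the 9 channels R,G,B,L*,a*,b*,H,S,V."""

    means: dict[str, float]
    stds: dict[str, float]


def image_size(
    img: RasterImage,
    method: Literal["sum", "product", "diagonal", "min", "max"] = "sum",
) -> float:
    """Image size from width and height; the default is their sum."""
    h, w = float(img.height), float(img.width)
    if method == "sum":
        return w + h
    if method == "product":
        return w * h
    if method == "diagonal":
        return float(np.hypot(w, h))
    if method == "min":
        return min(w, h)
    if method == "max":
        return max(w, h)
    raise ValueError(f"unknown size method {method!r}")


def aspect_ratio(img: RasterImage) -> float:
    """Width-to-height ratio (display-format convention)."""
    return img.width / img.height


def rms_contrast(img: LabImage) -> float:
    """RMS contrast: population SD of the CIELAB L* channel."""
    return float(np.std(img.L))


def shannon_entropy(values: np.ndarray, spec: HistogramSpec) -> float:
    """Shannon entropy (bits) of a binned value distribution.

    Bin proportions p_i come from an equal-width histogram over
    ``spec.range``; the 0*log(0) terms are dropped. The result lies in
    [0, log2(bins)].
    """
    counts, _ = np.histogram(np.ravel(values), bins=spec.bins, range=spec.range)
    total = counts.sum()
    if total == 0:
        return float("nan")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def lightness_entropy(img: LabImage, spec: HistogramSpec = LSTAR_HIST) -> float:
    """Shannon entropy of the L* channel histogram, in bits."""
    return shannon_entropy(img.L, spec)


def color_entropy(img: HSVImage, spec: HistogramSpec = HUE_HIST) -> float:
    """Shannon entropy of the hue channel histogram, in bits."""
    return shannon_entropy(img.H, spec)


def color_channel_stats(img: RasterImage) -> ChannelStats:
    """Mean and population SD for each of the 9 RGB/L*a*b*/HSV channels.

    Hue is treated as a plain linear variable on [0, 1); no circular
    statistics are applied (parity with the original per-channel scripts).
    """
    rgb = img.pixels.astype(np.float64)
    lab = convert_color(img, "lab")
    hsv = convert_color(img, "hsv")
    planes = {
        "R": rgb[..., 0],
        "G": rgb[..., 1],
        "B": rgb[..., 2],
        "L": lab.L,
        "a": lab.a,
        "b": lab.b,
        "H": hsv.H,
        "S": hsv.S,
        "V": hsv.V,
    }
    means = {k: float(np.mean(v)) for k, v in planes.items()}
    stds = {k: float(np.std(v)) for k, v in planes.items()}
    return ChannelStats(means=means, stds=stds)
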