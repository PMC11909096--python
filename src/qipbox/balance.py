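"""Pixel-based composition measures: Balance (APB), DCM, mirror symmetry,
and Homogeneity.

Perceptual mass follows the dark-heavy convention of the original
black-on-white stimuli (weight = 255 - gray) unless ``bright_heavy`` is
chosen (weight = gray), e.g. for portraits on dark grounds.

The Balance score compares perceptual mass over eight pairs of equally
sized areas: for each of the four main axes (vertical, horizontal, major
and minor diagonal), the two halves, and the two outer regions cut off by
a pair of lines parallel to the axis at the 25% / 75% positions of the
perpendicular extent (so the inner band's area equals the two outer areas
combined). Pixels whose rank falls on a region boundary are shared
fractionally between the two regions, which makes the two areas of every
pair exactly equal and keeps all scores covariant under reflections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.filters import threshold_otsu

from .io import GrayImage

__all__ = [
    "MassPolarity",
    "DegenerateImageWarning",
    "mass_image",
    "balance_score",
    "dcm_score",
    "mirror_symmetry",
    "homogeneity",
    "HomogeneityResult",
]

MassPolarity = Literal["dark_heavy", "bright_heavy"]


class DegenerateImageWarning(UserWarning):
    """A measure is undefined on this input (blank / constant image)."""


def mass_image(img: GrayImage, polarity: MassPolarity = "dark_heavy") -> np.ndarray:
    """Per-pixel perceptual mass on the 8-bit scale."""
    g = img.pixels
    if img.scale_tag == "lstar":
        g = g * 2.55
    if polarity == "dark_heavy":
        return 255.0 - g
    if polarity == "bright_heavy":
        return np.array(g, dtype=np.float64, copy=True)
    raise ValueError(f"unknown polarity {polarity!r}")


def _band_weights(d: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fractional membership of each pixel in the rank band [lo, hi].

    ``d`` assigns every pixel a signed position; pixels are ranked by ``d``
    and membership is the overlap of a pixel's rank interval with
    [lo*N, hi*N]. Ties (equal ``d``) share the overlap evenly, so the total
    membership is exactly (hi - lo) * N and the split depends only on the
    distribution of ``d`` (reflection-covariant).
    """
    flat = np.ravel(d)
    n = flat.size
    values, counts = np.unique(flat, return_counts=True)
    ends = np.cumsum(counts).astype(np.float64)
    starts = ends - counts
    overlap = np.clip(np.minimum(ends, hi * n) - np.maximum(starts, lo * n), 0.0, None)
    w_per_value = overlap / counts
    idx = np.searchsorted(values, flat)
    return w_per_value[idx].reshape(np.shape(d))


def _axis_coordinates(h: int, w: int) -> dict[str, np.ndarray]:
    """Signed positions perpendicular to each of the four main axes."""
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    return {
        "vertical": x,
        "horizontal": y,
        "major_diag": h * (x + 0.5) - w * (y + 0.5),
        "minor_diag": h * (x + 0.5) + w * (y + 0.5) - float(h * w),
    }


def area_pair_masses(mass: np.ndarray) -> dict[str, tuple[float, float]]:
    """Perceptual mass of both members of each of the eight area pairs."""
    h, w = mass.shape
    coords = _axis_coordinates(h, w)
    pairs: dict[str, tuple[float, float]] = {}
    for axis, d in coords.items():
        w_half = _band_weights(d, 0.0, 0.5)
        pairs[f"{axis}_halves"] = (
            float((mass * w_half).sum()),
            float((mass * (1.0 - w_half)).sum()),
        )
        w_low = _band_weights(d, 0.0, 0.25)
        w_high = _band_weights(d, 0.75, 1.0)
        pairs[f"{axis}_outer"] = (
            float((mass * w_low).sum()),
            float((mass * w_high).sum()),
        )
    return pairs


def balance_score(img: GrayImage, polarity: MassPolarity = "dark_heavy") -> float:
    """APB Balance score in percent; 0 = perfectly balanced.

    For each area pair, d = 100*|M1 - M2| / (M1 + M2); the score is the
    mean of the eight d values. A pair with zero total mass contributes 0
    (trivially balanced); a fully blank image returns NaN with a warning.
    """
    mass = mass_image(img, polarity)
    if mass.sum() <= 0:
        warnings.warn("blank image under chosen polarity: Balance undefined",
                      DegenerateImageWarning, stacklevel=2)
        return float("nan")
    ds = []
    for m1, m2 in area_pair_masses(mass).values():
        tot = m1 + m2
        ds.append(0.0 if tot <= 0 else 100.0 * abs(m1 - m2) / tot)
    return float(np.mean(ds))


def dcm_score(img: GrayImage, polarity: MassPolarity = "dark_heavy") -> float:
    """Deviation of the center of perceptual mass, in percent.

    Distance from the mass centroid (pixel-center coordinates) to the
    geometric center ((W-1)/2, (H-1)/2), as a percentage of the distance
    from the center to a corner pixel center. 0 = centered, 100 = all mass
    in one corner pixel.
    """
    mass = mass_image(img, polarity)
    total = mass.sum()
    if total <= 0:
        warnings.warn("blank image under chosen polarity: DCM undefined",
                      DegenerateImageWarning, stacklevel=2)
        return float("nan")
    h, w = mass.shape
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    cx = float((mass * x).sum() / total)
    cy = float((mass * y).sum() / total)
    gx, gy = (w - 1) / 2.0, (h - 1) / 2.0
    dist = np.hypot(cx - gx, cy - gy)
    max_dist = np.hypot(gx, gy)
    if max_dist == 0:  # 1x1 image
        return 0.0
    return float(100.0 * dist / max_dist)


def mirror_symmetry(img: GrayImage) -> float:
    """Mean mirror-symmetry score in percent.

    Per axis a, s_a = 100 * (1 - mean|I - m_a(I)| / range) where m_a
    reflects across the axis. Square images average the vertical,
    horizontal, main-diagonal, and anti-diagonal axes; rectangular images
    average the vertical and horizontal axes only. 100 = exactly symmetric.
    """
    g = img.pixels
    rng = 255.0 if img.scale_tag == "8bit" else 100.0
    scores = [
        100.0 * (1.0 - np.abs(g - g[:, ::-1]).mean() / rng),
        100.0 * (1.0 - np.abs(g - g[::-1, :]).mean() / rng),
    ]
    if g.shape[0] == g.shape[1]:
        scores.append(100.0 * (1.0 - np.abs(g - g.T).mean() / rng))
        anti = g[::-1, ::-1].T
        scores.append(100.0 * (1.0 - np.abs(g - anti).mean() / rng))
    return float(np.mean(scores))


@dataclass
class HomogeneityResult:
    """Normalized spatial entropies (percent) of the black-pixel distribution."""

    cells_pct: float
    rows_pct: float
    cols_pct: float
    final_pct: float


def _grid_boundaries(extent: int, cells: int) -> np.ndarray:
    return np.round(np.arange(cells + 1) * extent / cells).astype(int)


def _norm_entropy_pct(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    ent = -(p * np.log2(p)).sum()
    return float(100.0 * ent / np.log2(counts.size))


def homogeneity(img: GrayImage, n: int = 10, m: int = 10) -> HomogeneityResult:
    """Spatial homogeneity of the Otsu-binarized foreground over an n x m grid.

    The image is binarized with the Otsu threshold (black = strictly below);
    black pixels are counted per grid cell. Each component is the Shannon
    entropy of the respective count distribution (all cells / row sums /
    column sums) normalized by its maximum (log2 of the number of bins) and
    expressed in percent. ``final_pct`` is the mean of the row and column
    components. Constant images (Otsu undefined) and images with no black
    pixels return NaN with a warning.
    """
    g = img.pixels
    nan = HomogeneityResult(*(float("nan"),) * 4)
    if np.ptp(g) == 0:
        warnings.warn("constant image: Otsu threshold undefined",
                      DegenerateImageWarning, stacklevel=2)
        return nan
    thresh = threshold_otsu(g, nbins=256)
    black = g < thresh
    if not black.any():
        warnings.warn("no black pixels after binarization: Homogeneity undefined",
                      DegenerateImageWarning, stacklevel=2)
        return nan
    h, w = g.shape
    rb = _grid_boundaries(h, n)
    cb = _grid_boundaries(w, m)
    counts = np.zeros((n, m), dtype=np.int64)
    for i in range(n):
        for j in range(m):
            counts[i, j] = black[rb[i]:rb[i + 1], cb[j]:cb[j + 1]].sum()
    cells_pct = _norm_entropy_pct(counts.ravel())
    rows_pct = _norm_entropy_pct(counts.sum(axis=1))
    cols_pct = _norm_entropy_pct(counts.sum(axis=0))
    return HomogeneityResult(
        cells_pct=cells_pct,
        rows_pct=rows_pct,
        cols_pct=cols_pct,
        final_pct=(rows_pct + cols_pct) / 2.0,
    )
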