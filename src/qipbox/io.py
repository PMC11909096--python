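"""Image loading, color conversion, and standardized resizing policies.

Every measure in the package consumes the containers defined here. Loading
normalizes all inputs to 8-bit RGB (grayscale promoted, alpha composited
over white, 16-bit rescaled), so downstream code never branches on source
format. Color conversions are fixed to one convention for the whole suite:
sRGB primaries with D65 white for CIELAB, and the legacy 0.299/0.587/0.114
luma weights for the 8-bit gray conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Union

import numpy as np
from PIL import Image
from skimage.color import lab2rgb, rgb2hsv, rgb2lab
from skimage.transform import resize as _sk_resize

__all__ = [
    "RasterImage",
    "GrayImage",
    "LabImage",
    "HSVImage",
    "SizePolicy",
    "load_image",
    "convert_color",
    "standardize_size",
    "GRAY_WEIGHTS",
]

#: RGB -> gray luma weights (legacy ITU-R BT.601 convention).
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


class ImageLoadError(RuntimeError):
    """Raised when a file cannot be decoded into a valid raster image."""


@dataclass
class RasterImage:
    """8-bit RGB raster image: ``pixels`` is an H x W x 3 uint8 array."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"RasterImage needs HxWx3 pixels, got {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("zero-area image")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values outside [0, 255]")
            px = np.round(px).astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class GrayImage:
    """Single-channel image with a declared scale.

    ``scale_tag`` is ``"8bit"`` (values in [0, 255]) or ``"lstar"``
    (CIELAB L* in [0, 100]). Values are floats; generators and resizing may
    produce non-integer intensities on the 8-bit scale.
    """

    pixels: np.ndarray
    scale_tag: Literal["8bit", "lstar"] = "8bit"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"GrayImage needs HxW pixels, got {px.shape}")
        hi = 255.0 if self.scale_tag == "8bit" else 100.0
        if px.min() < -1e-9 or px.max() > hi + 1e-9:
            raise ValueError(
                f"gray values outside declared {self.scale_tag} range [0, {hi}]"
            )
        self.pixels = np.clip(px, 0.0, hi)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LabImage:
    """CIELAB planes: L* in [0, 100], a*/b* roughly in [-128, 127]."""

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray

    @property
    def height(self) -> int:
        return self.L.shape[0]

    @property
    def width(self) -> int:
        return self.L.shape[1]


@dataclass
class HSVImage:
    """HSV planes, each in [0, 1] (hue as a fraction of the full circle)."""

    H: np.ndarray
    S: np.ndarray
    V: np.ndarray

    @property
    def height(self) -> int:
        return self.H.shape[0]

    @property
    def width(self) -> int:
        return self.H.shape[1]


PolicyKind = Literal[
    "longest_side",
    "total_pixels",
    "fixed_square",
    "max_pixels_cap",
    "center_crop_square_pow2",
    "pad_square_mean_gray",
]


@dataclass(frozen=True)
class SizePolicy:
    """A named resizing/cropping/padding policy with a pixel target.

    kinds:
      longest_side           resize so the longer side equals ``value``
      total_pixels           resize so H*W is as close to ``value`` as
                             possible without exceeding it (aspect kept)
      fixed_square           resize to ``value`` x ``value`` (aspect dropped)
      max_pixels_cap         downscale only, largest size with H*W <= value
      center_crop_square_pow2  centered square crop, side = largest power of
                             two <= min(H, W); ``value`` ignored
      pad_square_mean_gray   pad to square of side max(H, W) with the mean
                             value; ``value`` ignored
    """

    kind: PolicyKind
    value: int = 0

    def __post_init__(self) -> None:
        needs_value = self.kind in (
            "longest_side",
            "total_pixels",
            "fixed_square",
            "max_pixels_cap",
        )
        if needs_value and self.value <= 0:
            raise ValueError(f"policy {self.kind} needs a positive value")


def load_image(path: Union[str, Path]) -> RasterImage:
    """Load a raster file (PNG/JPEG/TIFF/BMP/PGM/PPM) as 8-bit RGB.

    Grayscale inputs are promoted to three identical channels, alpha is
    composited over white, and 16-bit inputs are rescaled to 8-bit.
    """
    path = Path(path)
    if not path.exists():
        raise ImageLoadError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("I;16", "I;16B", "I;16L", "I"):
                arr = np.asarray(im, dtype=np.float64)
                arr = arr / 65535.0 * 255.0 if arr.max() > 255 else arr
                im = Image.fromarray(np.round(arr).astype(np.uint8))
            if im.mode in ("RGBA", "LA", "PA", "P"):
                im = im.convert("RGBA")
                bg = Image.new("RGBA", im.size, (255, 255, 255, 255))
                im = Image.alpha_composite(bg, im)
            im = im.convert("RGB")
            px = np.asarray(im, dtype=np.uint8)
    except ImageLoadError:
        raise
    except Exception as exc:  # decoding failure, truncated file, ...
        raise ImageLoadError(f"cannot read image {path}: {exc}") from exc
    if px.size == 0:
        raise ImageLoadError(f"zero-area image: {path}")
    return RasterImage(px, source_id=path.name)


def convert_color(
    img: RasterImage, target: Literal["gray8", "lab", "hsv"]
) -> Union[GrayImage, LabImage, HSVImage]:
    """Convert an 8-bit RGB image to gray (luma), CIELAB, or HSV."""
    px = img.pixels
    if target == "gray8":
        w = np.asarray(GRAY_WEIGHTS)
        g = px.astype(np.float64) @ w
        return GrayImage(np.clip(g, 0.0, 255.0), scale_tag="8bit")
    if target == "lab":
        lab = rgb2lab(px)  # sRGB, D65
        return LabImage(lab[..., 0], lab[..., 1], lab[..., 2])
    if target == "hsv":
        hsv = rgb2hsv(px)
        return HSVImage(hsv[..., 0], hsv[..., 1], hsv[..., 2])
    raise ValueError(f"unknown color target {target!r}")


def lab_to_rgb8(lab: LabImage) -> RasterImage:
    """Inverse CIELAB conversion back to 8-bit sRGB (in-gamut colors)."""
    stack = np.stack([lab.L, lab.a, lab.b], axis=-1)
    rgb = lab2rgb(stack)
    return RasterImage(np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8))


def _resize_array(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize with pixel-center alignment, preserving value range."""
    if arr.shape[:2] == shape:
        return arr.copy()
    return _sk_resize(
        arr.astype(np.float64),
        shape + arr.shape[2:],
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )


def _aspect_size_for_cap(h: int, w: int, cap: int) -> tuple[int, int]:
    """Largest aspect-preserving integer size with h'*w' <= cap (no upscaling)."""
    if h * w <= cap:
        return h, w
    s = np.sqrt(cap / (h * w))
    h2 = max(1, int(np.floor(h * s)))
    w2 = max(1, int(np.floor(w * s)))
    # floor can be slightly conservative; grow while staying under cap and
    # keeping the aspect ratio within rounding of the original
    while (h2 + 1) * max(1, int(np.floor(w * (h2 + 1) / h))) <= cap:
        h2 += 1
        w2 = max(1, int(np.floor(w * h2 / h)))
    return h2, w2


def standardize_size(
    img: Union[RasterImage, GrayImage], policy: SizePolicy
) -> Union[RasterImage, GrayImage]:
    """Apply a SizePolicy; returns the same container kind as the input."""
    is_raster = isinstance(img, RasterImage)
    arr = img.pixels.astype(np.float64)
    h, w = arr.shape[:2]

    if policy.kind == "longest_side":
        long_side = max(h, w)
        scale = policy.value / long_side
        if h >= w:
            new = (policy.value, max(1, int(round(w * scale))))
        else:
            new = (max(1, int(round(h * scale))), policy.value)
        out = _resize_array(arr, new)
    elif policy.kind == "total_pixels":
        out = _resize_array(arr, _aspect_size_for_cap_exact(h, w, policy.value))
    elif policy.kind == "fixed_square":
        out = _resize_array(arr, (policy.value, policy.value))
    elif policy.kind == "max_pixels_cap":
        out = _resize_array(arr, _aspect_size_for_cap(h, w, policy.value))
    elif policy.kind == "center_crop_square_pow2":
        side = 2 ** int(np.floor(np.log2(min(h, w))))
        top = (h - side) // 2
        left = (w - side) // 2
        out = arr[top : top + side, left : left + side].copy()
    elif policy.kind == "pad_square_mean_gray":
        side = max(h, w)
        fill = arr.mean(axis=(0, 1))
        if is_raster:
            out = np.empty((side, side, 3), dtype=np.float64)
            out[...] = fill
        else:
            out = np.full((side, side), float(fill), dtype=np.float64)
        top = (side - h) // 2
        left = (side - w) // 2
        out[top : top + h, left : left + w] = arr
    else:  # pragma: no cover - SizePolicy validates kind
        raise ValueError(f"unknown policy kind {policy.kind!r}")

    if is_raster:
        return RasterImage(np.round(np.clip(out, 0, 255)).astype(np.uint8),
                           source_id=img.source_id)
    return GrayImage(out, scale_tag=img.scale_tag)


def _aspect_size_for_cap_exact(h: int, w: int, target: int) -> tuple[int, int]:
    """Aspect-preserving size with h'*w' as close to ``target`` as possible
    without exceeding it (may upscale, unlike max_pixels_cap).

    Changes of at most one pixel per side are skipped: they are within the
    integer-rounding band of the scale factor, and skipping them makes the
    policy idempotent.
    """
    s = np.sqrt(target / (h * w))
    h2 = max(1, int(round(h * s)))
    w2 = max(1, int(round(w * s)))
    while h2 * w2 > target:  # rounding overshoot: trim the larger side
        if w2 >= h2 and w2 > 1:
            w2 -= 1
        elif h2 > 1:
            h2 -= 1
        else:
            break
    if h * w <= target and abs(h2 - h) <= 1 and abs(w2 - w) <= 1:
        return h, w
    return h2, w2
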