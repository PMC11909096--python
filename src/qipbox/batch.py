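"""Batch computation of QIPs over image folders into one CSV table.

The measure registry maps stable snake_case column names to compute
functions. Expensive intermediates (CIELAB conversion, the Gabor edge
field, the HOG pyramid, the CNN response stack) are computed once per image
and shared by all measures that need them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import balance as bal
from . import basic, cnn, gabor, hog, spectral
from .io import RasterImage, convert_color, load_image

logger = logging.getLogger("qipbox")

__all__ = ["RunConfig", "MeasureInfo", "list_measures", "run_batch",
           "compute_measures", "MEASURE_ORDER"]


@dataclass
class RunConfig:
    """Configuration of one batch run."""

    inputs: Sequence[Path]
    measures: Sequence[str]
    out: Optional[Path] = None
    seed: int = 0
    cnn_weights: Optional[Path] = None
    phog_resize: Optional[int] = hog.PHOG_DEFAULT_PIXELS
    complexity_resize: Optional[int] = None
    mass_polarity: bal.MassPolarity = "dark_heavy"
    params: dict = dc_field(default_factory=dict)


@dataclass(frozen=True)
class MeasureInfo:
    name: str
    module: str
    description: str
    parameters: str = ""


class _ImageContext:
    """Lazy shared intermediates for one image."""

    def __init__(self, img: RasterImage, config: RunConfig):
        self.img = img
        self.config = config
        self._cache: dict[str, object] = {}

    def get(self, key: str, fn: Callable[[], object]) -> object:
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    @property
    def lab(self):
        return self.get("lab", lambda: convert_color(self.img, "lab"))

    @property
    def hsv(self):
        return self.get("hsv", lambda: convert_color(self.img, "hsv"))

    @property
    def gray(self):
        return self.get("gray", lambda: convert_color(self.img, "gray8"))

    @property
    def channel_stats(self):
        return self.get("chan", lambda: basic.color_channel_stats(self.img))

    @property
    def edge_field(self):
        return self.get("edges", lambda: gabor.gabor_edge_field(self.gray))

    @property
    def phog(self):
        def build():
            from .io import SizePolicy, standardize_size

            img = self.img
            if self.config.phog_resize:
                img = standardize_size(
                    img, SizePolicy("total_pixels", self.config.phog_resize)
                )
            return hog.build_phog(hog.gradient_image(convert_color(img, "lab")))

        return self.get("phog", build)

    @property
    def bank(self):
        def make():
            if self.config.cnn_weights:
                return cnn.load_pretrained_bank(self.config.cnn_weights)
            return cnn.surrogate_bank(self.config.seed)

        return self.get("bank", make)

    @property
    def cnn_var(self):
        return self.get("cnn_var", lambda: cnn.cnn_variances(self.img, self.bank))


def _chan_mean(name: str):
    return lambda ctx: ctx.channel_stats.means[name]


def _chan_std(name: str):
    return lambda ctx: ctx.channel_stats.stds[name]


_REGISTRY: dict[str, tuple[Callable[[_ImageContext], float], MeasureInfo]] = {}


def _register(name: str, module: str, description: str, parameters: str = ""):
    def deco(fn):
        _REGISTRY[name] = (fn, MeasureInfo(name, module, description, parameters))
        return fn

    return deco


_register("img_size_sum", "basic", "width + height in pixels")(
    lambda ctx: basic.image_size(ctx.img, "sum"))
_register("aspect_ratio", "basic", "width / height")(
    lambda ctx: basic.aspect_ratio(ctx.img))
_register("rms_contrast", "basic", "SD of the CIELAB L* channel")(
    lambda ctx: basic.rms_contrast(ctx.lab))
_register("lightness_entropy", "basic",
          "Shannon entropy of the L* histogram (bits)", "bins=256")(
    lambda ctx: basic.lightness_entropy(ctx.lab))
_register("complexity_hog", "hog",
          "mean strength of the combined L*a*b* gradient image",
          "resize_to (optional total pixels)")(
    lambda ctx: hog.complexity_hog(ctx.img, ctx.config.complexity_resize))
_register("edge_density", "gabor",
          "summed Gabor edge responses over 24 orientations",
          "capped at 120000 pixels")(
    lambda ctx: gabor.edge_density(ctx.edge_field))

for _c in basic.CHANNEL_NAMES:
    _register(f"mean_{_c}", "basic", f"mean of the {_c} channel")(_chan_mean(_c))
for _c in basic.CHANNEL_NAMES:
    _register(f"std_{_c}", "basic", f"SD of the {_c} channel")(_chan_std(_c))

_register("color_entropy", "basic",
          "Shannon entropy of the hue histogram (bits)", "bins=256")(
    lambda ctx: basic.color_entropy(ctx.hsv))
_register("balance", "balance", "APB Balance score (%, 0 = balanced)",
          "polarity")(
    lambda ctx: bal.balance_score(ctx.gray, ctx.config.mass_polarity))
_register("dcm", "balance", "deviation of the center of mass (%)", "polarity")(
    lambda ctx: bal.dcm_score(ctx.gray, ctx.config.mass_polarity))
_register("mirror_symmetry", "balance", "mean mirror symmetry (%)")(
    lambda ctx: bal.mirror_symmetry(ctx.gray))
_register("homogeneity", "balance",
          "spatial entropy of the binarized foreground (%, rows/cols mean)",
          "n=m=10")(
    lambda ctx: bal.homogeneity(ctx.gray).final_pct)
_register("cnn_sym_lr", "cnn", "CNN left-right symmetry [0,1]")(
    lambda ctx: cnn.cnn_symmetry(ctx.img, ctx.bank, "lr"))
_register("cnn_sym_ud", "cnn", "CNN up-down symmetry [0,1]")(
    lambda ctx: cnn.cnn_symmetry(ctx.img, ctx.bank, "ud"))
_register("cnn_sym_lrud", "cnn", "combined CNN symmetry [0,1]")(
    lambda ctx: cnn.cnn_symmetry(ctx.img, ctx.bank, "lrud"))
_register("fourier_slope_spehar", "spectral",
          "amplitude-spectrum slope, Cook's-distance pruning")(
    lambda ctx: spectral.fourier_slope(ctx.img, "spehar").slope)
_register("fourier_slope_redies", "spectral",
          "power-spectrum slope, 10-256 cycles, log-binned")(
    lambda ctx: spectral.fourier_slope(ctx.img, "redies").slope)
_register("fourier_slope_mather", "spectral",
          "L* amplitude-spectrum slope, middle two quartiles")(
    lambda ctx: spectral.fourier_slope(ctx.img, "mather").slope)
_register("fourier_sigma", "spectral",
          "mean squared residual about the power-spectrum fit (raw points)")(
    lambda ctx: spectral.fourier_sigma(ctx.img, binned=False))
_register("fourier_sigma_binned", "spectral",
          "mean squared residual about the fit (log-binned points)")(
    lambda ctx: spectral.fourier_sigma(ctx.img, binned=True))
_register("fractal_dim_2d", "spectral",
          "2D box-counting dimension of the binarized boundary")(
    lambda ctx: spectral.fractal_dim_2d(ctx.img).D)
_register("fractal_dim_3d", "spectral",
          "3D differential box-counting dimension of the L* surface")(
    lambda ctx: spectral.fractal_dim_3d(ctx.img).D)
_register("self_sim_phog", "hog", "PHOG self-similarity [0,1]",
          "levels 1-3, 16 bins, resize to 100000 px")(
    lambda ctx: hog.phog_self_similarity(ctx.phog))
_register("self_sim_cnn", "cnn", "CNN self-similarity [0,1]", "8x8 grid")(
    lambda ctx: cnn.cnn_self_similarity(ctx.img, ctx.bank))
_register("anisotropy", "hog",
          "SD of the level-3 normalized orientation distribution")(
    lambda ctx: hog.anisotropy(ctx.phog))
_register("eoe_first", "gabor", "first-order edge-orientation entropy (bits)")(
    lambda ctx: gabor.first_order_eoe(ctx.edge_field))
_register("eoe_second", "gabor",
          "second-order edge-orientation entropy (bits)",
          "top 10000 edges, min pair distance 20 px")(
    lambda ctx: gabor.second_order_eoe(gabor.strongest_edges(ctx.edge_field)))
_register("cnn_sparseness", "cnn",
          "mean across-filter variance of pooled CNN responses", "n=8")(
    lambda ctx: ctx.cnn_var["sparseness"])
_register("cnn_variability", "cnn",
          "median across-space variance of pooled CNN responses", "n=8")(
    lambda ctx: ctx.cnn_var["variability"])

#: Stable column order of the full roster (46 measures).
MEASURE_ORDER = tuple(_REGISTRY.keys())


def list_measures() -> list[MeasureInfo]:
    """The documented measure schema, in CSV column order."""
    return [info for _, info in _REGISTRY.values()]


def compute_measures(
    img: RasterImage, measures: Sequence[str], config: Optional[RunConfig] = None
) -> dict[str, float]:
    """Compute the selected measures for one image."""
    if config is None:
        config = RunConfig(inputs=[], measures=measures)
    unknown = [m for m in measures if m not in _REGISTRY]
    if unknown:
        raise KeyError(f"unknown measures: {unknown}")
    ctx = _ImageContext(img, config)
    out: dict[str, float] = {}
    for name in measures:
        fn, _ = _REGISTRY[name]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", bal.DegenerateImageWarning)
            out[name] = float(fn(ctx))
    return out


def resolve_measures(selection: Sequence[str] | str) -> list[str]:
    """Expand 'all' and validate measure names against the registry."""
    if selection == "all" or selection == ["all"]:
        return list(MEASURE_ORDER)
    names = list(selection)
    unknown = [m for m in names if m not in _REGISTRY]
    if unknown:
        raise KeyError(
            f"unknown measures: {unknown}; see list_measures() for the schema"
        )
    return names


def run_batch(config: RunConfig) -> tuple[pd.DataFrame, int]:
    """Compute the selected measures for every input image.

    Returns the result table (one row per image, sorted by path, an
    ``error`` column holding the failure reason for unreadable images) and
    the number of failed images. Rows of failed images carry NA values.
    """
    paths = sorted(Path(p) for p in config.inputs)
    if not paths:
        raise ValueError("no input images")
    measures = resolve_measures(list(config.measures))
    rows = []
    n_failed = 0
    for path in paths:
        row: dict[str, object] = {"image": path.name}
        try:
            img = load_image(path)
            row.update(compute_measures(img, measures, config))
            row["error"] = ""
        except Exception as exc:
            logger.error("failed on %s: %s", path, exc)
            n_failed += 1
            for name in measures:
                row[name] = np.nan
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["image", *measures, "error"])
    if config.out is not None:
        df.to_csv(config.out, index=False, na_rep="", lineterminator="\n",
                  encoding="utf-8")
    return df, n_failed
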