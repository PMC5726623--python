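"""Gloss-layer segmentation and global highlight image statistics.

The gloss layer is the set of foreground pixels whose luminance exceeds
mean + 2 SD of the foreground luminance distribution; connected regions
use 8-connectivity. From the layer four statistics are derived (number,
mean size, percentage area and strength of the highlights) together with
three foreground contrast measures and the validity flags applied before
any regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .renderer import RenderedImage

__all__ = [
    "GlossLayer",
    "HighlightStatistics",
    "ContrastMeasures",
    "ValidityFlags",
    "segment_gloss_layer",
    "compute_statistics",
    "contrasts",
    "validity",
]

_CONN8 = np.ones((3, 3), dtype=int)
_WHITTLE_EPS = 1e-4


@dataclass
class GlossLayer:
    binary_mask: np.ndarray
    labels: np.ndarray
    n_components: int
    threshold: float


@dataclass
class HighlightStatistics:
    """number is per view; mean_size and strength are per component /
    per highlight pixel; pct_area is a fraction of the foreground."""

    number: float
    mean_size: float
    pct_area: float
    strength: float

    def as_dict(self) -> dict[str, float]:
        return {
            "number": self.number,
            "mean_size": self.mean_size,
            "pct_area": self.pct_area,
            "strength": self.strength,
        }


@dataclass
class ContrastMeasures:
    michelson: float
    space_avg_michelson: float
    space_avg_whittle: float


@dataclass
class ValidityFlags:
    empty_gloss_layer: bool
    clipped: bool

    @property
    def invalid(self) -> bool:
        return self.empty_gloss_layer or self.clipped


def segment_gloss_layer(image: RenderedImage) -> GlossLayer:
    """Threshold at mean + 2 SD (population SD) of the foreground
    luminance; strictly-greater comparison; 8-connected labelling.

    Background pixels are ignored throughout.
    """
    fg = image.foreground_mask
    if not np.any(fg):
        raise ValueError("empty foreground mask")
    lum = image.luminance[fg]
    threshold = float(lum.mean() + 2.0 * lum.std())
    mask = fg & (image.luminance > threshold)
    labels, n = ndimage.label(mask, structure=_CONN8)
    return GlossLayer(
        binary_mask=mask, labels=labels, n_components=int(n), threshold=threshold
    )


def compute_statistics(
    layer: GlossLayer, image: RenderedImage
) -> HighlightStatistics:
    """Four global statistics of the gloss layer.

    The highlight count is divided by the number of views so a stereo
    pair reports highlights per half-image. With an empty layer the
    statistics are undefined and returned as NaN.
    """
    n_px = int(layer.binary_mask.sum())
    if layer.n_components == 0:
        return HighlightStatistics(math.nan, math.nan, math.nan, math.nan)
    n_fg = int(image.foreground_mask.sum())
    return HighlightStatistics(
        number=layer.n_components / image.n_views,
        mean_size=n_px / layer.n_components,
        pct_area=n_px / n_fg,
        strength=float(image.luminance[layer.binary_mask].mean()),
    )


def contrasts(image: RenderedImage, window: int = 15) -> ContrastMeasures:
    """Michelson contrast over the foreground plus space-averaged
    Michelson and Whittle contrasts on a sliding square window.

    Each window is restricted to foreground pixels; per-window values are
    averaged over all foreground pixel positions. The Whittle contrast
    per window is (Lmax - Lmin) / Lmin with an epsilon floor on Lmin.
    The floor is relative (1e-4 of the mean foreground luminance) so that
    the measure stays invariant under multiplicative intensity scaling.
    """
    fg = image.foreground_mask
    if not np.any(fg):
        raise ValueError("empty foreground mask")
    lum = image.luminance
    lmax, lmin = float(lum[fg].max()), float(lum[fg].min())
    denom = lmax + lmin
    michelson = (lmax - lmin) / denom if denom > 0 else 0.0

    hi = np.where(fg, lum, -np.inf)
    lo = np.where(fg, lum, np.inf)
    wmax = ndimage.maximum_filter(hi, size=window, mode="constant", cval=-np.inf)
    wmin = ndimage.minimum_filter(lo, size=window, mode="constant", cval=np.inf)
    wmax, wmin = wmax[fg], wmin[fg]
    wsum = wmax + wmin
    mich = np.where(wsum > 0, (wmax - wmin) / np.where(wsum > 0, wsum, 1.0), 0.0)
    floor = _WHITTLE_EPS * max(float(lum[fg].mean()), 1e-12)
    whittle = (wmax - wmin) / np.maximum(wmin, floor)
    return ContrastMeasures(
        michelson=michelson,
        space_avg_michelson=float(mich.mean()),
        space_avg_whittle=float(whittle.mean()),
    )


def validity(image: RenderedImage, layer: GlossLayer) -> ValidityFlags:
    """Exclusion flags: an empty gloss layer or any foreground pixel at
    the clip ceiling makes the record invalid."""
    if image.rgb is not None:
        fg_rgb = image.rgb[image.foreground_mask]
        clipped = bool(np.any(fg_rgb >= image.clip_ceiling - 1e-12))
    else:
        clipped = bool(
            np.any(image.luminance[image.foreground_mask] >= image.clip_ceiling - 1e-12)
        )
    return ValidityFlags(empty_gloss_layer=layer.n_components == 0, clipped=clipped)
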