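"""Stain segmentation by excess-color contrast and automatic thresholding.

The segmentation follows a three-step scheme common in computerized
histomorphometry: (1) the section is kept in full RGB; (2) contrast for
the stain of interest is enhanced by the excess-color transform
``2*C - C1 - C2`` for the dominant stain channel ``C``; (3) the enhanced
map is binarized with an automatic threshold (Otsu's between-class
variance criterion by default), after which explicit add/remove rasters
can reproduce any manual correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

Channel = Literal["R", "G", "B"]

_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}

MARKERS = ("Lyve-1", "POSTN", "TNC", "CD45", "generic")


@dataclass
class SectionImage:
    """An RGB section raster with its physical scale and annotations.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array, channels ordered R, G, B.
    pixel_size_um
        Physical edge length of one pixel in micrometers.
    basal_polyline
        Ordered ``(N, 2)`` array of ``(row, col)`` vertices tracing the
        basal epithelial layer (epidermis/dermis junction), left to right.
    tissue_mask
        Optional ``(H, W)`` boolean raster restricting analysis to tissue.
    junction_depth_um
        Depth of the papillary/reticular dermis boundary, measured from
        the basal layer.
    """

    pixels: np.ndarray
    pixel_size_um: float
    basal_polyline: Optional[np.ndarray] = None
    tissue_mask: Optional[np.ndarray] = None
    junction_depth_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.basal_polyline is not None:
            poly = np.asarray(self.basal_polyline, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2:
                raise ValueError("basal_polyline must be an (N, 2) vertex array")
            h, w = self.pixels.shape[:2]
            if (
                poly[:, 0].min() < 0
                or poly[:, 0].max() > h - 1
                or poly[:, 1].min() < 0
                or poly[:, 1].max() > w - 1
            ):
                raise ValueError("basal_polyline lies outside the image bounds")
            self.basal_polyline = poly
        if self.tissue_mask is not None:
            tm = np.asarray(self.tissue_mask, dtype=bool)
            if tm.shape != self.pixels.shape[:2]:
                raise ValueError("tissue_mask shape must match image")
            self.tissue_mask = tm

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[:2]


@dataclass
class StainMask:
    """Binary stained/unstained raster for one marker on one section."""

    mask: np.ndarray
    marker: str = "generic"
    threshold_used: float = float("nan")
    manually_corrected: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D raster")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def area_um2(self, pixel_size_um: float) -> float:
        return self.area_px * pixel_size_um**2


def excess_color(image: SectionImage | np.ndarray, channel: Channel) -> np.ndarray:
    """Per-pixel excess of one RGB channel over the other two.

    Returns ``2*C - C1 - C2`` as a signed integer map in [-510, 510].
    The map is not clipped: thresholding operates on the full range.
    Adding a constant to all three channels leaves the map unchanged,
    which is what makes the transform robust to overall brightness.
    """
    if channel not in _CHANNEL_INDEX:
        raise ValueError(f"channel must be one of R, G, B, got {channel!r}")
    pixels = image.pixels if isinstance(image, SectionImage) else np.asarray(image)
    rgb = pixels.astype(np.int32)
    c = _CHANNEL_INDEX[channel]
    others = [i for i in range(3) if i != c]
    return 2 * rgb[..., c] - rgb[..., others[0]] - rgb[..., others[1]]


def _otsu_midpoint(values: np.ndarray, nbins: int) -> float:
    """Otsu's criterion on an ``nbins`` histogram of ``values``.

    The between-class variance is maximized over all bin splits; the
    returned threshold is the midpoint between the largest value of the
    low class and the smallest value of the high class, so binarizing
    with a strict ``value > threshold`` reproduces the maximizing
    partition exactly (a bin-center threshold would misassign values
    lying above the center of their own bin).
    """
    levels, weights = np.unique(values, return_counts=True)
    if levels.size > nbins:
        # continuous-valued map: quantize to nbins equal-width bins and
        # treat occupied bin centers as the candidate levels
        hist, edges = np.histogram(values, bins=nbins)
        centers = (edges[:-1] + edges[1:]) / 2.0
        occupied = hist > 0
        levels = centers[occupied]
        weights = hist[occupied]
    w = weights / weights.sum()
    cw = np.cumsum(w)
    cmu = np.cumsum(w * levels)
    mu_total = cmu[-1]
    cw_low = cw[:-1]  # split after level k keeps at least one level high
    bcv = (mu_total * cw_low - cmu[:-1]) ** 2 / (cw_low * (1.0 - cw_low))
    k = int(np.argmax(bcv))
    boundary = (levels[k] + levels[k + 1]) / 2.0
    low = values[values < boundary]
    high = values[values >= boundary]
    return float((low.max() + high.min()) / 2.0)


def auto_threshold(
    scalar_map: np.ndarray,
    mask: Optional[np.ndarray] = None,
    nbins: int = 256,
    method: str = "otsu",
) -> float:
    """Automatic threshold on a scalar map, maximizing between-class variance.

    Uses Otsu's criterion over a ``nbins``-bin histogram of the (optionally
    masked) values; the threshold falls strictly between the two classes.
    Raises on a degenerate (constant) map, where no threshold separates
    two classes.
    """
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    values = np.asarray(scalar_map, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("mask shape must match map")
        values = values[mask]
    values = values.ravel()
    if values.size == 0:
        raise ValueError("no pixels to threshold")
    if np.all(values == values[0]):
        raise ValueError(
            "degenerate histogram: map is constant inside the mask, "
            "no threshold can separate two classes"
        )
    return _otsu_midpoint(values, nbins)


def binarize(
    scalar_map: np.ndarray,
    threshold: float,
    marker: str = "generic",
    tissue_mask: Optional[np.ndarray] = None,
) -> StainMask:
    """Binarize a scalar map: a pixel is stained iff its value > threshold.

    Ties (value == threshold) are unstained. When a tissue mask is given,
    pixels outside it are unstained regardless of value.
    """
    if not np.isfinite(threshold):
        # sentinel below the minimum is allowed and yields a full mask
        if np.isnan(threshold):
            raise ValueError("threshold must not be NaN")
    mask = np.asarray(scalar_map) > threshold
    if tissue_mask is not None:
        mask = mask & np.asarray(tissue_mask, dtype=bool)
    return StainMask(mask=mask, marker=marker, threshold_used=float(threshold))


def apply_manual_correction(
    stain: StainMask,
    add_mask: Optional[np.ndarray] = None,
    remove_mask: Optional[np.ndarray] = None,
) -> StainMask:
    """Apply explicit add/remove correction rasters to a stain mask.

    The result is ``(mask | add) & ~remove``. A pixel present in both the
    add and the remove raster is ambiguous and raises. The corrected mask
    is flagged ``manually_corrected`` when either raster is non-empty.
    """
    mask = stain.mask
    add = np.zeros_like(mask) if add_mask is None else np.asarray(add_mask, dtype=bool)
    rem = (
        np.zeros_like(mask) if remove_mask is None else np.asarray(remove_mask, dtype=bool)
    )
    if add.shape != mask.shape or rem.shape != mask.shape:
        raise ValueError("correction rasters must share the mask's dimensions")
    overlap = add & rem
    if overlap.any():
        raise ValueError(
            f"ambiguous correction: {int(overlap.sum())} pixel(s) present in "
            "both add and remove rasters"
        )
    corrected = (mask | add) & ~rem
    touched = bool(add.any() or rem.any())
    return StainMask(
        mask=corrected,
        marker=stain.marker,
        threshold_used=stain.threshold_used,
        manually_corrected=stain.manually_corrected or touched,
    )


def segment_stain(
    image: SectionImage,
    channel: Channel = "R",
    marker: str = "generic",
    nbins: int = 256,
) -> StainMask:
    """Full three-step segmentation: excess color, Otsu threshold, binarize.

    Convenience wrapper equal to
    ``binarize(excess_color(img, ch), auto_threshold(...))`` with the
    image's tissue mask applied at both stages.
    """
    emap = excess_color(image, channel)
    thr = auto_threshold(emap, mask=image.tissue_mask, nbins=nbins)
    return binarize(emap, thr, marker=marker, tissue_mask=image.tissue_mask)
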