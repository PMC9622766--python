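"""Collagen scar index from polarized-light picrosirius red images.

Under crossed polarizers, picrosirius-red-stained collagen birefringes
with a color that tracks fiber thickness and packing: thick, densely
packed fibers (mainly type I collagen) appear red-orange, thin fibers
(mainly type III) appear green. Classifying pixels by hue therefore
separates the two populations, and their area ratio — the *scar
index* — rises with scarring fibrosis.

Classification runs in HSV space. A pixel is considered fiber signal
when its value (brightness) and saturation clear configurable floors;
it is labelled thick when its hue falls in the red-orange window and
thin when in the green window. Hue windows default to the conventional
picrosirius bands (red-orange 0-50 deg plus the wrap-around 340-360
deg; green 70-160 deg). Yellow hues between the windows are left
unassigned rather than forced into either class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from skimage.color import rgb2hsv

from .profiling import DepthMap
from .segmentation import SectionImage

HueWindow = Tuple[float, float]  # degrees on the hue circle, lo <= hi

DEFAULT_THICK_HUE: Tuple[HueWindow, ...] = ((0.0, 50.0), (340.0, 360.0))
DEFAULT_THIN_HUE: Tuple[HueWindow, ...] = ((70.0, 160.0),)
DEFAULT_MIN_SATURATION = 0.2
DEFAULT_MIN_VALUE = 0.1


@dataclass
class FiberMasks:
    """Thick (red-orange) and thin (green) birefringent fiber masks."""

    thick_mask: np.ndarray
    thin_mask: np.ndarray
    thick_hue_deg: Tuple[HueWindow, ...] = DEFAULT_THICK_HUE
    thin_hue_deg: Tuple[HueWindow, ...] = DEFAULT_THIN_HUE
    min_saturation: float = DEFAULT_MIN_SATURATION
    min_value: float = DEFAULT_MIN_VALUE

    def __post_init__(self) -> None:
        self.thick_mask = np.asarray(self.thick_mask, dtype=bool)
        self.thin_mask = np.asarray(self.thin_mask, dtype=bool)
        if self.thick_mask.shape != self.thin_mask.shape:
            raise ValueError("thick and thin masks differ in shape")
        if (self.thick_mask & self.thin_mask).any():
            raise ValueError("a pixel cannot be both thick and thin fiber")


@dataclass
class ScarIndexResult:
    """Thick/thin fiber areas and their ratio for one dermal compartment."""

    thick_area_um2: float
    thin_area_um2: float
    compartment: str

    @property
    def defined(self) -> bool:
        return self.thin_area_um2 > 0

    @property
    def scar_index(self) -> float:
        if not self.defined:
            return float("nan")
        return self.thick_area_um2 / self.thin_area_um2


def _in_windows(hue_deg: np.ndarray, windows: Sequence[HueWindow]) -> np.ndarray:
    out = np.zeros(hue_deg.shape, dtype=bool)
    for lo, hi in windows:
        out |= (hue_deg >= lo) & (hue_deg <= hi)
    return out


def _validate_windows(
    thick: Sequence[HueWindow], thin: Sequence[HueWindow]
) -> None:
    for name, wins in (("thick", thick), ("thin", thin)):
        for lo, hi in wins:
            if not (0.0 <= lo < hi <= 360.0):
                raise ValueError(f"{name} hue window ({lo}, {hi}) is not valid")
    for lo1, hi1 in thick:
        for lo2, hi2 in thin:
            if max(lo1, lo2) < min(hi1, hi2):
                raise ValueError(
                    f"thick window ({lo1}, {hi1}) overlaps thin window "
                    f"({lo2}, {hi2}): classification would be ambiguous"
                )


def classify_birefringence(
    image: SectionImage,
    thick_hue_deg: Sequence[HueWindow] = DEFAULT_THICK_HUE,
    thin_hue_deg: Sequence[HueWindow] = DEFAULT_THIN_HUE,
    min_saturation: float = DEFAULT_MIN_SATURATION,
    min_value: float = DEFAULT_MIN_VALUE,
) -> FiberMasks:
    """Label thick (red-orange) and thin (green) fiber pixels by hue.

    Pixels below the value or saturation floor — the dark background of
    a crossed-polarizer capture, or achromatic glare — stay unassigned,
    as do hues between the two windows (yellow transition colors).
    """
    _validate_windows(thick_hue_deg, thin_hue_deg)
    hsv = rgb2hsv(image.pixels)
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]
    signal = (val >= min_value) & (sat >= min_saturation)
    if image.tissue_mask is not None:
        signal &= image.tissue_mask
    thick = signal & _in_windows(hue, thick_hue_deg)
    thin = signal & _in_windows(hue, thin_hue_deg) & ~thick
    return FiberMasks(
        thick_mask=thick,
        thin_mask=thin,
        thick_hue_deg=tuple(thick_hue_deg),
        thin_hue_deg=tuple(thin_hue_deg),
        min_saturation=min_saturation,
        min_value=min_value,
    )


def scar_index(
    masks: FiberMasks,
    dmap: DepthMap,
    junction_depth_um: float,
) -> Tuple[ScarIndexResult, ScarIndexResult]:
    """Scar index (thick/thin area ratio) per dermal compartment.

    Fiber areas are summed separately for pixels shallower than the
    papillary/reticular junction depth and for those at or below it.
    A compartment without thin-fiber signal yields a result flagged
    undefined rather than an infinite ratio.
    """
    if masks.thick_mask.shape != dmap.depth_um.shape:
        raise ValueError("fiber masks and depth map dimensions differ")
    px_area = dmap.pixel_size_um**2
    dermis = ~dmap.excluded
    papillary_zone = dermis & (dmap.depth_um < junction_depth_um)
    reticular_zone = dermis & (dmap.depth_um >= junction_depth_um)
    results = []
    for zone, name in ((papillary_zone, "papillary"), (reticular_zone, "reticular")):
        thick_area = float((masks.thick_mask & zone).sum()) * px_area
        thin_area = float((masks.thin_mask & zone).sum()) * px_area
        results.append(
            ScarIndexResult(
                thick_area_um2=thick_area, thin_area_um2=thin_area, compartment=name
            )
        )
    return results[0], results[1]
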