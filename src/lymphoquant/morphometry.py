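"""Paw-swelling normalization and tissue-layer thickness morphometry.

Swelling is expressed per animal as ``(T / Tc) * 100`` — operated-paw
thickness relative to the contralateral control paw — which removes
inter-animal size variability. Layer (epidermis or dermis) thickness is
measured at several sites spread along the band and summarised as
median and interquartile range; group effects are reported as ratios
of medians, matching the nonparametric summaries used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import ndimage


@dataclass
class LayerThicknessResult:
    """Thickness of one tissue band measured at several sites."""

    layer: str
    measurements_um: np.ndarray

    def __post_init__(self) -> None:
        self.measurements_um = np.asarray(self.measurements_um, dtype=float)
        if np.any(self.measurements_um <= 0):
            raise ValueError("thickness measurements must be positive")

    @property
    def median_um(self) -> float:
        return float(np.median(self.measurements_um))

    @property
    def iqr_um(self) -> Tuple[float, float]:
        lo, hi = np.percentile(self.measurements_um, [25, 75])
        return float(lo), float(hi)


def normalize_paw(T_mm: float, Tc_mm: float) -> float:
    """Operated-paw thickness as a percentage of the control paw: (T/Tc)*100."""
    if Tc_mm <= 0:
        raise ValueError("control paw thickness Tc must be positive")
    return T_mm / Tc_mm * 100.0


def layer_thickness(
    layer_mask: np.ndarray,
    pixel_size_um: float,
    n_sites: int = 5,
    seed: int | None = None,
    layer: str = "dermis",
    max_fragmentation: float = 0.05,
) -> LayerThicknessResult:
    """Measure a band's thickness at ``n_sites`` stations along its axis.

    The band's principal axis is estimated from the pixel coordinates
    (PCA); stations sit at the centers of ``n_sites`` equal strata along
    that axis (a seed jitters them within their stratum). At each
    station, thickness is the band's extent perpendicular to the axis
    within a thin slab, converted to micrometers. This makes the
    measurement independent of the band's orientation in the image.
    """
    mask = np.asarray(layer_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty layer mask")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    labels, n_comp = ndimage.label(mask)
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, labels, index=range(1, n_comp + 1))
        main = sizes.max()
        if (mask.sum() - main) / mask.sum() > max_fragmentation:
            raise ValueError(
                f"layer mask fragmented into {n_comp} components; "
                "thickness along a band is ill-defined"
            )
        mask = labels == (int(np.argmax(sizes)) + 1)

    coords = np.column_stack(np.nonzero(mask)).astype(float)
    center = coords.mean(axis=0)
    centered = coords - center
    cov = centered.T @ centered / len(centered)
    eigval, eigvec = np.linalg.eigh(cov)
    axis = eigvec[:, np.argmax(eigval)]  # long axis of the band
    normal = eigvec[:, np.argmin(eigval)]
    along = centered @ axis
    across = centered @ normal

    lo, hi = along.min(), along.max()
    if hi - lo <= 0:
        raise ValueError("degenerate band: no extent along its axis")
    rng = np.random.default_rng(seed)
    strata = np.linspace(lo, hi, n_sites + 1)
    slab_half = max((hi - lo) / (20 * n_sites), 1.0)
    measurements = []
    for i in range(n_sites):
        s_lo, s_hi = strata[i], strata[i + 1]
        station = (s_lo + s_hi) / 2
        if seed is not None:
            # jitter within the central half of the stratum
            station = rng.uniform(
                s_lo + 0.25 * (s_hi - s_lo), s_hi - 0.25 * (s_hi - s_lo)
            )
        slab = np.abs(along - station) <= slab_half
        if not slab.any():
            raise ValueError(
                f"no band pixels near station {i + 1}: band too fragmented"
            )
        extent = across[slab].max() - across[slab].min() + 1.0
        measurements.append(extent * pixel_size_um)
    return LayerThicknessResult(layer=layer, measurements_um=np.array(measurements))


def fold_change(
    ld_values: Sequence[float], control_values: Sequence[float]
) -> float:
    """Ratio of group medians, median(LD) / median(control).

    Medians rather than means, consistent with the median +/- IQR
    summaries used for all group outcomes. Returns NaN (flagged
    undefined) when the control median is zero.
    """
    ld = np.asarray(ld_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if ld.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be non-empty")
    m_ctrl = float(np.median(ctrl))
    if m_ctrl == 0:
        return float("nan")
    return float(np.median(ld)) / m_ctrl
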