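"""Synthetic skin sections, polarized scenes, ICG series and paw cohorts.

Every generator returns exact ground truth alongside the data, so each
downstream stage (segmentation, depth profiling, scar index, clearance
AUC, morphometry, statistics) can be scored as a parameter-recovery
problem. The scenes emulate the structure of mouse hind-limb skin
sections: a superficial epidermis band, a flat basal epithelial layer,
a papillary dermis above a configurable junction depth and a reticular
dermis below it, and stain blobs whose depth distribution and total
area are generator parameters. Polarized-light scenes place fiber
pixels in a red-orange (thick fiber) or green (thin fiber) hue band on
a dark background. ICG series follow a single-exponential decay sampled
at the standard 0/1/3/5/7 h schedule; paw cohorts follow the four-group
irradiation/surgery design (n = 8, 7, 11, 13).

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .clearance import ClearanceSeries, auc_1_5
from .segmentation import SectionImage

# default scene palette: eosin-like background, a red-dominant chromogen,
# a hematoxylin-like epidermis band and brown follicle profiles
BACKGROUND_RGB = (235, 228, 224)
STAIN_RGB = (160, 60, 55)
EPIDERMIS_RGB = (200, 185, 205)
FOLLICLE_RGB = (120, 105, 95)

# four-group design of the irradiation/surgery lymphedema model
GROUP_LABELS = {
    1: "post-Surgery",
    2: "post-Irradiation",
    3: "post-Surgery/Irradiation",
    4: "post-Irradiation/Surgery",
}
GROUP_SIZES = (8, 7, 11, 13)


# --------------------------------------------------------------------------
# depth distributions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Uniform:
    """Blob depths uniform on [lo_um, hi_um] below the basal layer."""

    lo_um: float
    hi_um: float

    def __post_init__(self):
        if not 0 <= self.lo_um < self.hi_um:
            raise ValueError("need 0 <= lo_um < hi_um")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lo_um, self.hi_um, size=n)

    @property
    def max_um(self) -> float:
        return self.hi_um


@dataclass(frozen=True)
class Point:
    """All blobs at one fixed depth."""

    d_um: float

    def __post_init__(self):
        if self.d_um < 0:
            raise ValueError("depth must be non-negative")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, self.d_um)

    @property
    def max_um(self) -> float:
        return self.d_um


@dataclass(frozen=True)
class Mixture:
    """Weighted mixture of depth distributions."""

    components: Tuple[Union["Uniform", "Point"], ...]
    weights: Tuple[float, ...]

    def __post_init__(self):
        if len(self.components) != len(self.weights) or not self.components:
            raise ValueError("components and weights must be non-empty, same length")
        if any(w < 0 for w in self.weights) or sum(self.weights) <= 0:
            raise ValueError("weights must be non-negative with positive sum")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        w = w / w.sum()
        choice = rng.choice(len(self.components), size=n, p=w)
        out = np.empty(n)
        for i, comp in enumerate(self.components):
            sel = choice == i
            out[sel] = comp.sample(rng, int(sel.sum()))
        return out

    @property
    def max_um(self) -> float:
        return max(c.max_um for c in self.components)


DepthDistribution = Union[Uniform, Point, Mixture]


# --------------------------------------------------------------------------
# scene specification and ground truth
# --------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """Parameters of one synthetic skin-section scene.

    The scene is an ``image_height_px x image_width_px`` RGB raster at
    ``pixel_size_um`` per pixel: an epidermis band at the top, the basal
    layer at ``epidermis_thickness_um``, papillary dermis down to
    ``junction_depth_um`` below the basal layer, reticular dermis
    beneath. ``blob_count`` circular stain blobs of ``blob_radius_px``
    are placed at depths drawn from ``depth_distribution``.
    """

    image_height_px: int = 400
    image_width_px: int = 600
    pixel_size_um: float = 0.23
    epidermis_thickness_um: float = 20.0
    junction_depth_um: float = 350.0
    blob_count: int = 100
    blob_radius_px: float = 2.0
    depth_distribution: DepthDistribution = field(
        default_factory=lambda: Uniform(40.0, 320.0)
    )
    stain_color: Tuple[int, int, int] = STAIN_RGB
    background_color: Tuple[int, int, int] = BACKGROUND_RGB
    noise_sd: float = 0.0
    seed: int = 0
    allow_overlap: bool = True
    n_follicles: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        depth_extent_um = (
            self.image_height_px * self.pixel_size_um - self.epidermis_thickness_um
        )
        if not (0 < self.epidermis_thickness_um):
            raise ValueError("epidermis_thickness_um must be positive")
        if not (self.epidermis_thickness_um < self.junction_depth_um):
            raise ValueError(
                "junction_depth_um must exceed epidermis_thickness_um"
            )
        if self.junction_depth_um >= depth_extent_um + self.epidermis_thickness_um:
            raise ValueError("junction_depth_um exceeds the tissue depth extent")
        if self.blob_count < 0:
            raise ValueError("blob_count must be non-negative")
        if self.blob_radius_px <= 0:
            raise ValueError("blob_radius_px must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("stain_color", "background_color"):
            col = getattr(self, name)
            if len(col) != 3 or any(not (0 <= v <= 255) for v in col):
                raise ValueError(f"{name} must be an RGB triple in [0, 255]^3")
        if self.depth_distribution.max_um > depth_extent_um:
            raise ValueError(
                "depth_distribution extends beyond the dermis depth extent "
                f"({self.depth_distribution.max_um:.1f} > {depth_extent_um:.1f} um)"
            )


@dataclass
class GroundTruth:
    """Exact generator-side truth for one synthetic dataset."""

    total_stain_area_um2: float = 0.0
    depth_samples_um: Optional[np.ndarray] = None
    true_p90_um: float = float("nan")
    thick_area_um2: float = float("nan")
    thin_area_um2: float = float("nan")
    true_auc: float = float("nan")
    # per-compartment fiber areas for polarized scenes
    thick_area_by_compartment: Optional[Dict[str, float]] = None
    thin_area_by_compartment: Optional[Dict[str, float]] = None


def _disk_offsets(radius: float) -> Tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    inside = dr**2 + dc**2 <= radius**2
    return dr[inside], dc[inside]


def generate_skin_section(spec: SceneSpec) -> Tuple[SectionImage, GroundTruth]:
    """Render one synthetic skin section and its exact ground truth.

    The basal layer is a flat horizontal polyline at the epidermis
    thickness. Blob centers are placed at the sampled depths below it;
    any blob pixel that would cross upward into the epidermis is clipped
    at the basal layer, so rendered stain never invades the epidermis.
    Ground truth records the exact rendered stained pixel count (after
    clipping and overlap) converted to µm², the sampled centroid depths
    and their empirical 0.9 quantile. Identical spec + seed gives a
    bitwise-identical image.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height_px, spec.image_width_px
    px = spec.pixel_size_um
    img = np.empty((h, w, 3), dtype=float)
    img[:] = spec.background_color

    basal_row = spec.epidermis_thickness_um / px
    img[: int(np.ceil(basal_row)), :] = EPIDERMIS_RGB

    # hair follicles: vertical ellipses confined to the papillary dermis
    junction_row = basal_row + spec.junction_depth_um / px
    for _ in range(spec.n_follicles):
        fc = rng.uniform(10, w - 10)
        f_top = basal_row + 2
        f_bot = min(junction_row - 2, basal_row + 0.6 * (junction_row - basal_row))
        rows, cols = np.mgrid[0:h, 0:w]
        ell = ((rows - (f_top + f_bot) / 2) / ((f_bot - f_top) / 2 + 1e-9)) ** 2 + (
            (cols - fc) / 4.0
        ) ** 2 <= 1
        img[ell] = FOLLICLE_RGB

    stain = np.zeros((h, w), dtype=bool)
    depths = np.empty(0)
    if spec.blob_count > 0:
        depths = spec.depth_distribution.sample(rng, spec.blob_count)
        center_rows = basal_row + depths / px
        center_cols = rng.uniform(
            spec.blob_radius_px, w - 1 - spec.blob_radius_px, size=spec.blob_count
        )
        if not spec.allow_overlap:
            center_rows, center_cols = _place_without_overlap(
                rng, center_rows, center_cols, spec, basal_row
            )
        dr, dc = _disk_offsets(spec.blob_radius_px)
        for r0, c0 in zip(center_rows, center_cols):
            rr = (np.round(r0).astype(int) + dr).astype(int)
            cc = (np.round(c0).astype(int) + dc).astype(int)
            keep = (rr >= basal_row) & (rr < h) & (cc >= 0) & (cc < w)
            stain[rr[keep], cc[keep]] = True
        img[stain] = spec.stain_color

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    polyline = np.array([[basal_row, 0.0], [basal_row, w - 1.0]])
    tissue = np.ones((h, w), dtype=bool)
    section = SectionImage(
        pixels=img,
        pixel_size_um=px,
        basal_polyline=polyline,
        tissue_mask=tissue,
        junction_depth_um=spec.junction_depth_um,
    )
    truth = GroundTruth(
        total_stain_area_um2=float(stain.sum()) * px**2,
        depth_samples_um=depths,
        true_p90_um=float(np.quantile(depths, 0.9)) if depths.size else float("nan"),
    )
    return section, truth


def _place_without_overlap(
    rng: np.random.Generator,
    center_rows: np.ndarray,
    center_cols: np.ndarray,
    spec: SceneSpec,
    basal_row: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Re-draw blob columns by dart throwing until no two blobs overlap.

    Depth (row) samples are preserved — only the lateral position is
    re-drawn — so the depth ground truth is untouched. Uses a uniform
    grid hash for neighbor lookups. Raises when the scene is too crowded
    to place every blob.
    """
    n = center_rows.size
    r = spec.blob_radius_px
    min_d2 = (2 * r) ** 2
    cell = max(2 * r, 1.0)
    grid: Dict[Tuple[int, int], List[int]] = {}
    rows_out = np.empty(n)
    cols_out = np.empty(n)
    w = spec.image_width_px
    max_attempts = 200
    for i in range(n):
        row = center_rows[i]
        placed = False
        for _ in range(max_attempts):
            col = rng.uniform(r, w - 1 - r)
            key = (int(row // cell), int(col // cell))
            ok = True
            for kr in range(key[0] - 1, key[0] + 2):
                for kc in range(key[1] - 1, key[1] + 2):
                    for j in grid.get((kr, kc), ()):
                        if (rows_out[j] - row) ** 2 + (cols_out[j] - col) ** 2 < min_d2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                rows_out[i] = row
                cols_out[i] = col
                grid.setdefault(key, []).append(i)
                placed = True
                break
        if not placed:
            raise ValueError(
                "non-overlap constraint violated: could not place blob "
                f"{i + 1}/{n} of radius {r} px after {max_attempts} attempts; "
                "scene too crowded"
            )
    return rows_out, cols_out


# --------------------------------------------------------------------------
# polarized-light scenes
# --------------------------------------------------------------------------

# hue bands (degrees) used when rendering fiber pixels; chosen to sit
# centrally inside the conventional picrosirius classification windows
_THICK_HUE_DEG = (10.0, 40.0)
_THIN_HUE_DEG = (90.0, 150.0)


def _hsv_to_rgb_scalar(h_deg: float, s: float, v: float) -> Tuple[int, int, int]:
    import colorsys

    r, g, b = colorsys.hsv_to_rgb(h_deg / 360.0, s, v)
    return int(round(r * 255)), int(round(g * 255)), int(round(b * 255))


def generate_polarized_section(
    spec: SceneSpec, thick_fraction: float
) -> Tuple[SectionImage, GroundTruth]:
    """Render a polarized-light picrosirius scene with known fiber classes.

    ``blob_count`` is reused as the number of single-pixel fiber sites;
    a fraction ``thick_fraction`` of them (rounded) is rendered in the
    red-orange band (thick, type-I-like collagen) and the rest in the
    green band (thin, type-III-like). The background is near-black, as
    under crossed polarizers. Ground truth carries exact thick/thin
    areas overall and per dermal compartment.
    """
    if not 0.0 <= thick_fraction <= 1.0:
        raise ValueError("thick_fraction must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height_px, spec.image_width_px
    px = spec.pixel_size_um
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[:] = (8, 8, 8)

    basal_row = spec.epidermis_thickness_um / px
    n = spec.blob_count
    n_thick = int(round(n * thick_fraction))

    depths = spec.depth_distribution.sample(rng, n) if n else np.empty(0)
    rows = np.clip(np.round(basal_row + depths / px).astype(int), 0, h - 1)
    cols = rng.integers(0, w, size=n)
    # deduplicate sites so ground-truth label counts equal rendered pixels
    seen = set()
    keep = np.ones(n, dtype=bool)
    for i, (r0, c0) in enumerate(zip(rows, cols)):
        if (r0, c0) in seen:
            keep[i] = False
        else:
            seen.add((r0, c0))
    while not keep.all():
        redo = np.flatnonzero(~keep)
        cols[redo] = rng.integers(0, w, size=redo.size)
        for i in redo:
            if (rows[i], cols[i]) in seen:
                keep[i] = False
            else:
                seen.add((rows[i], cols[i]))
                keep[i] = True

    is_thick = np.zeros(n, dtype=bool)
    is_thick[:n_thick] = True

    thick_by_comp = {"papillary": 0.0, "reticular": 0.0}
    thin_by_comp = {"papillary": 0.0, "reticular": 0.0}
    for i in range(n):
        if is_thick[i]:
            hue = rng.uniform(*_THICK_HUE_DEG)
        else:
            hue = rng.uniform(*_THIN_HUE_DEG)
        sat = rng.uniform(0.75, 1.0)
        val = rng.uniform(0.6, 1.0)
        img[rows[i], cols[i]] = _hsv_to_rgb_scalar(hue, sat, val)
        comp = "papillary" if depths[i] < spec.junction_depth_um else "reticular"
        if is_thick[i]:
            thick_by_comp[comp] += px**2
        else:
            thin_by_comp[comp] += px**2

    polyline = np.array([[basal_row, 0.0], [basal_row, w - 1.0]])
    section = SectionImage(
        pixels=img,
        pixel_size_um=px,
        basal_polyline=polyline,
        tissue_mask=np.ones((h, w), dtype=bool),
        junction_depth_um=spec.junction_depth_um,
    )
    truth = GroundTruth(
        total_stain_area_um2=n * px**2,
        depth_samples_um=depths,
        true_p90_um=float(np.quantile(depths, 0.9)) if depths.size else float("nan"),
        thick_area_um2=n_thick * px**2,
        thin_area_um2=(n - n_thick) * px**2,
        thick_area_by_compartment=thick_by_comp,
        thin_area_by_compartment=thin_by_comp,
    )
    return section, truth


# --------------------------------------------------------------------------
# ICG clearance series
# --------------------------------------------------------------------------


def generate_icg_series(
    i0: float,
    k_per_h: float,
    timepoints_h: Sequence[float] = (0.0, 1.0, 3.0, 5.0, 7.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    animal_id: str = "animal-1",
    limb: str = "LD",
) -> Tuple[ClearanceSeries, GroundTruth]:
    """Single-exponential ICG intensity series with exact AUC ground truth.

    ``intensity(t) = i0 * exp(-k_per_h * t) + noise``. The true AUC is
    the trapezoid over the *noise-free* values on the 1-5 h window,
    matching how the pipeline integrates measured points.
    """
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    if k_per_h < 0:
        raise ValueError("k_per_h must be non-negative")
    t = np.asarray(timepoints_h, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be sorted strictly ascending")
    if 1.0 not in t or 5.0 not in t:
        raise ValueError(
            "timepoints must include 1 h and 5 h: the clearance AUC window "
            "is undefined otherwise"
        )
    rng = np.random.default_rng(seed)
    clean = i0 * np.exp(-k_per_h * t)
    noisy = clean + (rng.normal(0.0, noise_sd, size=t.size) if noise_sd > 0 else 0.0)
    noisy = np.maximum(noisy, 0.0)
    series = ClearanceSeries(
        animal_id=animal_id, limb=limb, timepoints_h=t, mean_intensity=noisy
    )
    window = (t >= 1.0) & (t <= 5.0)
    true_auc = float(np.trapezoid(clean[window], t[window]))
    return series, GroundTruth(true_auc=true_auc)


# --------------------------------------------------------------------------
# paw-swelling cohorts
# --------------------------------------------------------------------------


def generate_paw_cohort(
    group_sizes: Sequence[int] = GROUP_SIZES,
    fold_by_group_day: Optional[pd.DataFrame] = None,
    baseline_mm: float = 2.0,
    baseline_sd_mm: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a four-group paw-thickness cohort.

    ``fold_by_group_day`` is a long table with columns ``group``, ``day``
    and ``fold`` giving the true swelling fold per group and measurement
    day; by default each group is measured at day 28 with folds
    (1.1, 1.2, 2.75, 3.0), i.e. little swelling after a single
    intervention and 2.5-3x after combined treatment. Per animal and
    day, the control-paw thickness Tc is drawn around ``baseline_mm``
    and the operated thickness is ``fold * Tc`` plus measurement noise.
    """
    if len(group_sizes) != 4:
        raise ValueError("expected four group sizes")
    if any(n < 0 for n in group_sizes):
        raise ValueError("group sizes must be non-negative")
    if fold_by_group_day is None:
        fold_by_group_day = pd.DataFrame(
            {"group": [1, 2, 3, 4], "day": [28] * 4, "fold": [1.1, 1.2, 2.75, 3.0]}
        )
    if (fold_by_group_day["fold"] <= 0).any():
        raise ValueError("folds must be positive")
    rng = np.random.default_rng(seed)
    records = []
    animal_no = 0
    for g, n in zip((1, 2, 3, 4), group_sizes):
        folds_g = fold_by_group_day[fold_by_group_day["group"] == g]
        for _ in range(n):
            animal_no += 1
            aid = f"m{animal_no:03d}"
            tc = max(rng.normal(baseline_mm, baseline_sd_mm), 0.2)
            for _, row in folds_g.iterrows():
                t = row["fold"] * tc + (
                    rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                )
                t = max(t, 0.05)
                records.append(
                    {
                        "animal_id": aid,
                        "group": g,
                        "group_label": GROUP_LABELS[g],
                        "day": int(row["day"]),
                        "T_mm": t,
                        "Tc_mm": tc,
                        "relative_percent": t / tc * 100.0,
                    }
                )
    return pd.DataFrame.from_records(records)


# --------------------------------------------------------------------------
# canonical study scenes
# --------------------------------------------------------------------------


def control_scene_spec(
    seed: int = 7,
    blob_count: int = 5000,
    pixel_size_um: float = 1.0,
) -> SceneSpec:
    """Default control-limb scene: capillaries confined to the papillary dermis.

    In control skin the lymphatic capillaries sit around hair follicles
    within the papillary dermis, so blob depths are uniform on
    [40, 320] µm — entirely above the 350 µm papillary/reticular
    junction — which puts the P90 in the 225-300 µm range seen in
    control sections.
    """
    return SceneSpec(
        image_height_px=420,
        image_width_px=2200,
        pixel_size_um=pixel_size_um,
        epidermis_thickness_um=20.0,
        junction_depth_um=350.0,
        blob_count=blob_count,
        blob_radius_px=2.0,
        depth_distribution=Uniform(40.0, 320.0),
        noise_sd=0.0,
        seed=seed,
        n_follicles=6,
    )


def fold_cohort_specs(
    area_ratio: float,
    n_per_arm: int = 21,
    seed: int = 1,
    control_blobs: int = 300,
    ld_max_depth_um: float = 700.0,
    noise_sd: float = 5.0,
    pixel_size_um: float = 1.0,
) -> List[Tuple[SceneSpec, SceneSpec]]:
    """Paired control/LD scene specs at a known stain-area ratio.

    Each pair shares nothing but the design: the control arm carries
    ``control_blobs`` capillary-sized blobs confined to the papillary
    dermis, the LD arm ``round(area_ratio * control_blobs)`` blobs
    reaching down to ``ld_max_depth_um``. Blobs are placed without
    overlap so the rendered stain area scales exactly with the blob
    count, making ``area_ratio`` the true integrated-area fold change.
    """
    if area_ratio <= 0:
        raise ValueError("area_ratio must be positive")
    rng = np.random.default_rng(seed)
    height = int(np.ceil(ld_max_depth_um + 80.0) / pixel_size_um)
    pairs = []
    for _ in range(n_per_arm):
        s1 = int(rng.integers(0, 2**31 - 1))
        s2 = int(rng.integers(0, 2**31 - 1))
        common = dict(
            image_height_px=height,
            image_width_px=700,
            pixel_size_um=pixel_size_um,
            epidermis_thickness_um=20.0,
            junction_depth_um=350.0,
            blob_radius_px=2.0,
            noise_sd=noise_sd,
            allow_overlap=False,
        )
        control = SceneSpec(
            blob_count=control_blobs,
            depth_distribution=Uniform(40.0, 320.0),
            seed=s1,
            **common,
        )
        ld = SceneSpec(
            blob_count=int(round(area_ratio * control_blobs)),
            depth_distribution=Uniform(40.0, ld_max_depth_um),
            seed=s2,
            **common,
        )
        pairs.append((control, ld))
    return pairs


def lymphedema_scene_spec(
    seed: int = 8,
    blob_count: int = 5000,
    pixel_size_um: float = 1.0,
    max_depth_um: float = 700.0,
) -> SceneSpec:
    """Lymphedematous scene: stain extends deep into the reticular dermis."""
    return SceneSpec(
        image_height_px=int(np.ceil((max_depth_um + 60.0) / pixel_size_um)),
        image_width_px=2200,
        pixel_size_um=pixel_size_um,
        epidermis_thickness_um=20.0,
        junction_depth_um=350.0,
        blob_count=blob_count,
        blob_radius_px=2.0,
        depth_distribution=Uniform(40.0, max_depth_um),
        noise_sd=0.0,
        seed=seed,
        n_follicles=6,
    )
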