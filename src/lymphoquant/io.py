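"""File formats and run configuration.

Images are 8-bit RGB TIFF or PNG. Per-section annotations travel as
JSON with the basal polyline as a vertex list in 0-based ``[row, col]``
pixel coordinates ordered left to right, the papillary/reticular
junction depth in micrometers and the pixel size in µm/px. Tables are
CSV with a header row, UTF-8, "." decimal separator. A run manifest
(JSON) records every parameter and seed so a run can be re-executed
exactly from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import imageio.v3 as iio
import numpy as np
import tifffile

from .segmentation import SectionImage


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write an 8-bit image as TIFF or PNG, chosen by the file suffix."""
    path = Path(path)
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def write_annotation(
    path: str | Path,
    basal_polyline: np.ndarray,
    pixel_size_um: float,
    junction_depth_um: float,
    extra: Optional[Dict] = None,
) -> None:
    """Write a per-section annotation JSON."""
    payload = {
        "pixel_size_um": float(pixel_size_um),
        "junction_depth_um": float(junction_depth_um),
        "basal_polyline_rc": np.asarray(basal_polyline, dtype=float).tolist(),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_annotation(path: str | Path) -> Dict:
    return json.loads(Path(path).read_text())


def load_section(image_path: str | Path, annotation_path: str | Path) -> SectionImage:
    """Assemble a SectionImage from an image file and its annotation JSON."""
    pixels = read_image(image_path)
    ann = read_annotation(annotation_path)
    return SectionImage(
        pixels=pixels,
        pixel_size_um=ann["pixel_size_um"],
        basal_polyline=np.asarray(ann["basal_polyline_rc"], dtype=float),
        junction_depth_um=ann.get("junction_depth_um"),
    )


_CONFIG_FIELDS: Dict[str, object] = {}


@dataclass
class RunConfig:
    """Validated parameters of an end-to-end pipeline run."""

    input_dir: str = "."
    out_dir: str = "results"
    pixel_size_um: float = 0.23
    bin_width_um: float = 10.0
    junction_depth_um: float = 350.0
    channel: str = "R"
    marker: str = "generic"
    threshold_method: str = "otsu"
    adjust: Optional[str] = None
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "bin_width_um", "junction_depth_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.channel not in ("R", "G", "B"):
            raise ValueError("channel must be one of R, G, B")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from JSON or simple key=value lines.

        Unknown keys are rejected rather than silently ignored.
        """
        text = Path(path).read_text()
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            raw = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"cannot parse config line: {line!r}")
                key, val = (s.strip() for s in line.split("=", 1))
                raw[key] = val
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = {}
        for key, val in raw.items():
            default = getattr(cls, key, None)
            fdef = {f.name: f for f in dataclasses.fields(cls)}[key]
            if isinstance(val, str) and fdef.type in ("float", float):
                val = float(val)
            elif isinstance(val, str) and fdef.type in ("int", int):
                val = int(val)
            elif isinstance(val, str) and fdef.type in ("bool", bool):
                val = val.lower() in ("1", "true", "yes")
            coerced[key] = val
        return cls(**coerced)

    def to_manifest(self) -> Dict:
        return dataclasses.asdict(self)


def write_manifest(path: str | Path, config: RunConfig, extra: Optional[Dict] = None) -> None:
    payload = {"config": config.to_manifest()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_manifest(path: str | Path) -> Dict:
    return json.loads(Path(path).read_text())
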