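import numpy as np
import pytest

from lymphoquant import synthetic as syn


@pytest.fixture
def uniform_section():
    """Noise-free section with 10,000 blobs uniform on [0, 324.4] um."""
    spec = syn.SceneSpec(
        image_height_px=400,
        image_width_px=3000,
        pixel_size_um=1.0,
        epidermis_thickness_um=20.0,
        junction_depth_um=350.0,
        blob_count=10_000,
        blob_radius_px=2.0,
        depth_distribution=syn.Uniform(0.0, 324.4),
        noise_sd=0.0,
        seed=42,
    )
    return syn.generate_skin_section(spec)


@pytest.fixture
def small_section():
    """Small noise-free section for fast per-operation checks."""
    spec = syn.SceneSpec(
        image_height_px=300,
        image_width_px=400,
        pixel_size_um=1.0,
        epidermis_thickness_um=20.0,
        junction_depth_um=150.0,
        blob_count=200,
        blob_radius_px=2.0,
        depth_distribution=syn.Uniform(10.0, 250.0),
        noise_sd=0.0,
        seed=3,
    )
    return syn.generate_skin_section(spec)
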