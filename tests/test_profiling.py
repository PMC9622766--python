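"""Depth maps, distribution curves, P90, integrated area, compartments."""

import numpy as np
import pytest

from lymphoquant.profiling import (
    DepthMap,
    DepthProfile,
    depth_map,
    depth_profile,
    mean_profile,
    polyline_distance,
    split_compartments,
)
from lymphoquant.segmentation import SectionImage, StainMask, segment_stain


def _flat_section(h=120, w=80, px=0.23, basal_row=0.0):
    img = np.zeros((h, w, 3), dtype=np.uint8)
    poly = np.array([[basal_row, 0.0], [basal_row, w - 1.0]])
    return SectionImage(pixels=img, pixel_size_um=px, basal_polyline=poly)


def test_depth_map_straight_line_distance():
    section = _flat_section(px=0.23)
    dmap = depth_map(section)
    assert dmap.depth_um[100, 10] == pytest.approx(23.0)
    assert dmap.depth_um[0, 40] == 0.0  # on the polyline


def test_depth_map_epidermal_side_excluded():
    section = _flat_section(basal_row=20.0)
    dmap = depth_map(section)
    assert dmap.excluded[:20, :].all()
    assert not dmap.excluded[20:, :].any()


def test_depth_map_degenerate_polyline_fails():
    img = np.zeros((10, 10, 3), dtype=np.uint8)
    section = SectionImage(
        pixels=img, pixel_size_um=1.0, basal_polyline=np.array([[0.0, 5.0]])
    )
    with pytest.raises(ValueError, match="degenerate|two vertices"):
        depth_map(section)


def _brute_force_distance(point, polyline):
    best = np.inf
    for a, b in zip(polyline[:-1], polyline[1:]):
        ab = b - a
        denom = ab @ ab
        t = 0.0 if denom == 0 else np.clip((point - a) @ ab / denom, 0.0, 1.0)
        best = min(best, np.linalg.norm(point - (a + t * ab)))
    return best


def test_depth_map_matches_brute_force_on_jagged_polylines():
    """Exact point-to-segment distances, checked against a scalar loop."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n_vert = rng.integers(3, 9)
        poly = np.column_stack(
            [rng.uniform(0, 29, n_vert), np.sort(rng.uniform(0, 29, n_vert))]
        )
        pts = rng.uniform(0, 29, size=(15, 2))
        fast = polyline_distance(pts, poly)
        slow = [_brute_force_distance(p, poly) for p in pts]
        np.testing.assert_allclose(fast, slow, rtol=1e-12, atol=1e-12)


def test_depth_profile_point_mass():
    """All stain at one depth: a single bin, P90 at that depth."""
    section = _flat_section(h=100, w=50, px=1.0)
    dmap = depth_map(section)
    mask = np.zeros((100, 50), bool)
    mask[50, :] = True  # depth exactly 50 um
    prof = depth_profile(StainMask(mask), dmap, bin_width_um=10.0)
    nonzero = np.flatnonzero(prof.stained_area_per_bin_um2)
    assert nonzero.size == 1
    assert prof.bin_edges_um[nonzero[0]] == 50.0
    assert prof.p90_um == pytest.approx(50.0)


def test_depth_profile_area_arithmetic():
    """1,000 stained px at 0.23 um/px -> integrated area 52.9 um^2."""
    section = _flat_section(h=100, w=100, px=0.23)
    dmap = depth_map(section)
    mask = np.zeros((100, 100), bool)
    mask.ravel()[:1000] = True
    prof = depth_profile(StainMask(mask), dmap, bin_width_um=10.0)
    assert prof.integrated_area_um2 == pytest.approx(1000 * 0.23**2)
    assert prof.integrated_area_um2 == pytest.approx(52.9)


def test_depth_profile_empty_mask_flagged_not_raised():
    section = _flat_section()
    dmap = depth_map(section)
    prof = depth_profile(StainMask(np.zeros((120, 80), bool)), dmap, 10.0)
    assert prof.integrated_area_um2 == 0.0
    assert not prof.p90_defined
    assert np.isnan(prof.p90_um)


def test_depth_profile_uniform_p90_recovery(uniform_section):
    section, truth = uniform_section
    mask = segment_stain(section, channel="R")
    dmap = depth_map(section)
    prof = depth_profile(mask, dmap, bin_width_um=10.0)
    assert abs(prof.p90_um - truth.true_p90_um) / truth.true_p90_um <= 0.02
    # close to the analytic 0.9 quantile of uniform [0, 324.4]
    assert prof.p90_um == pytest.approx(0.9 * 324.4, rel=0.02)


def test_bin_width_robustness(uniform_section):
    section, _ = uniform_section
    mask = segment_stain(section, channel="R")
    dmap = depth_map(section)
    p_fine = depth_profile(mask, dmap, bin_width_um=5.0).p90_um
    p_coarse = depth_profile(mask, dmap, bin_width_um=20.0).p90_um
    assert abs(p_fine - p_coarse) <= 20.0


def test_scale_equivariance():
    """Doubling the pixel size doubles depths and quadruples areas."""
    h, w = 120, 80
    mask = np.zeros((h, w), bool)
    rng = np.random.default_rng(5)
    mask[rng.integers(10, h, 200), rng.integers(0, w, 200)] = True
    profs = {}
    for px in (1.0, 2.0):
        section = _flat_section(h=h, w=w, px=px)
        dmap = depth_map(section)
        profs[px] = depth_profile(StainMask(mask), dmap, bin_width_um=10.0 * px)
    assert profs[2.0].integrated_area_um2 == pytest.approx(
        4.0 * profs[1.0].integrated_area_um2
    )
    assert profs[2.0].p90_um == pytest.approx(2.0 * profs[1.0].p90_um)


def test_mean_profile_identity_and_idempotence():
    edges = np.arange(0.0, 60.0, 10.0)
    prof = DepthProfile(edges, np.array([1.0, 2.0, 3.0, 0.0, 4.0]))
    single = mean_profile([prof])
    np.testing.assert_allclose(
        single.stained_area_per_bin_um2, prof.stained_area_per_bin_um2
    )
    double = mean_profile([prof, prof])
    np.testing.assert_allclose(
        double.stained_area_per_bin_um2, prof.stained_area_per_bin_um2
    )


def test_mean_profile_two_point_masses():
    """Equal-area point masses at 100 and 300 um: mean-curve P90 = 300."""
    edges = np.arange(0.0, 320.0, 10.0)
    a = np.zeros(edges.size - 1)
    b = np.zeros(edges.size - 1)
    a[10] = 50.0  # bin [100, 110)
    b[30] = 50.0  # bin [300, 310)
    mean = mean_profile([DepthProfile(edges, a), DepthProfile(edges, b)])
    assert mean.p90_um == pytest.approx(300.0)
    assert mean.integrated_area_um2 == pytest.approx(50.0)


def test_mean_profile_empty_list_fails():
    with pytest.raises(ValueError):
        mean_profile([])


def test_split_conservation_and_pro_rata():
    edges = np.arange(0.0, 110.0, 10.0)
    areas = np.full(10, 7.0)  # uniform curve over [0, 100)
    prof = DepthProfile(edges, areas)
    pap, ret = split_compartments(prof, 25.0)  # junction at 25% of range
    assert pap.integrated_area_um2 == pytest.approx(0.25 * prof.integrated_area_um2)
    assert (
        pap.integrated_area_um2 + ret.integrated_area_um2
        == pytest.approx(prof.integrated_area_um2, abs=1e-12)
    )


def test_split_at_bin_edge_exact_partition():
    edges = np.arange(0.0, 60.0, 10.0)
    areas = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    pap, ret = split_compartments(DepthProfile(edges, areas), 20.0)
    assert pap.integrated_area_um2 == pytest.approx(3.0)
    assert ret.integrated_area_um2 == pytest.approx(12.0)


def test_split_junction_beyond_last_bin():
    edges = np.arange(0.0, 60.0, 10.0)
    areas = np.ones(5)
    pap, ret = split_compartments(DepthProfile(edges, areas), 1000.0)
    assert ret.integrated_area_um2 == 0.0
    assert pap.integrated_area_um2 == pytest.approx(5.0)


def test_split_conservation_on_pipeline_profile(small_section):
    section, _ = small_section
    mask = segment_stain(section, channel="R")
    dmap = depth_map(section)
    prof = depth_profile(mask, dmap, bin_width_um=10.0)
    pap, ret = split_compartments(prof, section.junction_depth_um)
    assert pap.integrated_area_um2 + ret.integrated_area_um2 == pytest.approx(
        prof.integrated_area_um2, rel=1e-12
    )
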