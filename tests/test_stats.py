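"""Binwise Mann-Whitney, Kruskal-Wallis/Dunn, two-way ANOVA/Tukey, Spearman."""

import itertools

import numpy as np
import pytest

from lymphoquant.profiling import DepthProfile
from lymphoquant.stats import (
    compare_profiles_pointwise,
    kruskal_dunn,
    spearman,
    two_way_anova_tukey,
)


def _profiles(matrix, width=10.0):
    edges = np.arange(matrix.shape[1] + 1) * width
    return [DepthProfile(edges, row) for row in matrix]


def test_identical_groups_give_p_one_everywhere():
    rng = np.random.default_rng(0)
    mat = rng.uniform(0, 50, size=(4, 6))
    res = compare_profiles_pointwise(_profiles(mat), _profiles(mat.copy()))
    np.testing.assert_allclose(res.p_per_bin, 1.0)


def test_exact_mann_whitney_worked_example():
    """Completely separated 3 vs 3: exact two-sided p = 2/20 = 0.1."""
    a = np.array([[1.0], [2.0], [3.0]])
    b = np.array([[10.0], [20.0], [30.0]])
    res = compare_profiles_pointwise(_profiles(a), _profiles(b))
    assert res.p_per_bin[0] == pytest.approx(0.1)


def _enumerate_exact_p(a, b):
    """Oracle: enumerate every assignment of pooled ranks to group A and
    form the exact two-sided p as twice the smaller tail probability."""
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(pooled)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u_min = min(u_obs, n1 * (n - n1) - u_obs)
    count = total = 0
    for comb in itertools.combinations(range(n), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if u <= u_min:
            count += 1
    return min(2.0 * count / total, 1.0)


def test_exact_p_matches_enumeration_oracle():
    rng = np.random.default_rng(7)
    for _ in range(5):
        a = rng.uniform(0, 100, 4).round(3)
        b = rng.uniform(0, 100, 4).round(3)
        res = compare_profiles_pointwise(
            _profiles(a.reshape(-1, 1)), _profiles(b.reshape(-1, 1))
        )
        oracle = _enumerate_exact_p(a, b)
        assert res.p_per_bin[0] == pytest.approx(oracle)


def test_rank_invariance_under_monotone_transform():
    rng = np.random.default_rng(3)
    a = rng.uniform(1, 50, size=(5, 4))
    b = rng.uniform(1, 50, size=(5, 4))
    raw = compare_profiles_pointwise(_profiles(a), _profiles(b)).p_per_bin
    logd = compare_profiles_pointwise(
        _profiles(np.log(a)), _profiles(np.log(b))
    ).p_per_bin
    np.testing.assert_allclose(raw, logd)


def test_bh_adjustment_never_below_raw():
    rng = np.random.default_rng(5)
    a = rng.uniform(0, 50, size=(6, 8))
    b = rng.uniform(0, 50, size=(6, 8)) + rng.uniform(0, 30, 8)
    res = compare_profiles_pointwise(_profiles(a), _profiles(b), adjust="bh")
    assert np.all(res.adjusted_p_per_bin >= res.p_per_bin - 1e-12)


def test_too_few_profiles_rejected():
    mat = np.ones((2, 3))
    with pytest.raises(ValueError, match="at least 3"):
        compare_profiles_pointwise(_profiles(mat), _profiles(mat))


def test_kruskal_identical_groups():
    res = kruskal_dunn([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    assert res["H"] == pytest.approx(0.0, abs=1e-12)
    assert res["p"] == pytest.approx(1.0)


def test_kruskal_dunn_extreme_group_has_smallest_p():
    res = kruskal_dunn([[1, 2], [3, 4], [100, 101]])
    p = res["dunn_p"]
    off_diag = [
        p.loc["group1", "group2"],
        p.loc["group1", "group3"],
        p.loc["group2", "group3"],
    ]
    assert p.loc["group1", "group3"] == min(off_diag)


def test_kruskal_empty_group_fails():
    with pytest.raises(ValueError, match="empty"):
        kruskal_dunn([[1.0, 2.0], []])


def test_kruskal_type_one_error_calibrated():
    """Null rejection rate at alpha = 0.05 lies in [0.03, 0.07]."""
    rng = np.random.default_rng(2024)
    rejections = 0
    n_sim = 1000
    for _ in range(n_sim):
        groups = [rng.normal(0, 1, 10) for _ in range(4)]
        if kruskal_dunn(groups)["p"] < 0.05:
            rejections += 1
    assert 0.03 <= rejections / n_sim <= 0.07


def test_anova_all_equal_degenerate():
    out = two_way_anova_tukey(
        [5.0] * 16, ["LD", "control"] * 8, [1, 1, 2, 2, 3, 3, 4, 4] * 2
    )
    assert out["degenerate"] is True
    assert (out["anova"]["F"] == 0.0).all()
    assert (out["anova"]["p"] == 1.0).all()


def test_anova_zero_error_with_effects_flagged():
    """Cell means differ but residual variance is zero: flagged, not inf."""
    values, limbs, groups = [], [], []
    for l, mu in (("LD", 10.0), ("control", 5.0)):
        for g in (1, 2):
            for _ in range(2):
                values.append(mu + g)
                limbs.append(l)
                groups.append(g)
    out = two_way_anova_tukey(values, limbs, groups)
    assert out["degenerate"] is True


def test_anova_matches_hand_computed_sums_of_squares():
    rng = np.random.default_rng(3)
    values, limbs, groups = [], [], []
    eff_l = {"LD": 2.0, "control": 0.0}
    for l in ("LD", "control"):
        for g in (1, 2, 3, 4):
            for _ in range(5):
                values.append(10 + eff_l[l] + g + rng.normal(0, 1))
                limbs.append(l)
                groups.append(g)
    out = two_way_anova_tukey(values, limbs, groups)
    y = np.array(values).reshape(2, 4, 5)
    gm = y.mean()
    ss_l = 20 * ((y.mean(axis=(1, 2)) - gm) ** 2).sum()
    ss_g = 10 * ((y.mean(axis=(0, 2)) - gm) ** 2).sum()
    cell = y.mean(axis=2)
    ss_int = 5 * (
        (
            cell
            - y.mean(axis=(1, 2))[:, None]
            - y.mean(axis=(0, 2))[None, :]
            + gm
        )
        ** 2
    ).sum()
    ss_err = ((y - cell[:, :, None]) ** 2).sum()
    f_l = (ss_l / 1) / (ss_err / 32)
    f_g = (ss_g / 3) / (ss_err / 32)
    f_i = (ss_int / 3) / (ss_err / 32)
    table = out["anova"]
    assert table.loc["limb", "F"] == pytest.approx(f_l)
    assert table.loc["group", "F"] == pytest.approx(f_g)
    assert table.loc["limb:group", "F"] == pytest.approx(f_i)
    assert out["tukey"] is not None


def test_anova_empty_cell_named_in_error():
    with pytest.raises(ValueError, match="limb=LD, group=2"):
        two_way_anova_tukey(
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            ["LD", "LD", "control", "control", "control", "control"],
            [1, 1, 1, 1, 2, 2],
        )


def test_spearman_worked_example_and_extremes():
    res = spearman([1, 2, 3, 4], [2, 1, 4, 3])
    # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (1,1,1,1): 1 - 24/60 = 0.6
    assert res["rho"] == pytest.approx(0.6)
    assert res["rho2"] == pytest.approx(0.36)
    inc = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
    assert inc["rho"] == pytest.approx(1.0)
    dec = spearman([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
    assert dec["rho"] == pytest.approx(-1.0)


def test_spearman_self_correlation_is_one():
    rng = np.random.default_rng(8)
    x = rng.uniform(0, 10, 15)
    assert spearman(x, x)["rho"] == pytest.approx(1.0)


def test_spearman_constant_input_flagged():
    res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
    assert res["defined"] is False
    assert np.isnan(res["rho"])
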