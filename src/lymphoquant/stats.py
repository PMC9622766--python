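"""Group statistics for pipeline outputs.

Four comparisons cover the study designs encountered here:

* binwise (point-by-point) two-sided Mann-Whitney U between two groups
  of depth-distribution curves, one test per depth bin — raw p-values
  by default, with an optional Benjamini-Hochberg column since dozens
  of bins are tested;
* Kruskal-Wallis across several groups with Dunn's pairwise post-hoc
  (Bonferroni-adjusted by default);
* two-way ANOVA (limb x experimental group) with Tukey HSD pairwise
  comparisons;
* Spearman rank correlation, reported as rho, rho^2 and two-sided p.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .profiling import DepthProfile


@dataclass
class CurveComparison:
    """Per-bin p-values from a point-by-point curve comparison."""

    bin_edges_um: np.ndarray
    p_per_bin: np.ndarray
    adjusted_p_per_bin: Optional[np.ndarray] = None
    method: str = "mann-whitney"

    def __post_init__(self) -> None:
        self.bin_edges_um = np.asarray(self.bin_edges_um, dtype=float)
        self.p_per_bin = np.asarray(self.p_per_bin, dtype=float)
        if self.bin_edges_um.size != self.p_per_bin.size + 1:
            raise ValueError("need one p-value per bin")
        if np.any((self.p_per_bin < 0) | (self.p_per_bin > 1)):
            raise ValueError("p-values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "depth_lo_um": self.bin_edges_um[:-1],
                "depth_hi_um": self.bin_edges_um[1:],
                "p": self.p_per_bin,
            }
        )
        if self.adjusted_p_per_bin is not None:
            out["p_adjusted"] = self.adjusted_p_per_bin
        return out


def _mannwhitney_bin(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p for one bin.

    Exact null when the combined sample is small and tie-free,
    tie-corrected normal approximation otherwise. A bin in which every
    value is identical carries no evidence either way: p = 1.
    """
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def compare_profiles_pointwise(
    group_a: Sequence[DepthProfile],
    group_b: Sequence[DepthProfile],
    adjust: Optional[str] = None,
) -> CurveComparison:
    """Point-by-point Mann-Whitney comparison of two groups of curves.

    Each depth bin contributes one two-sided test on the per-section
    stained areas in that bin. ``adjust="bh"`` adds a
    Benjamini-Hochberg-adjusted column; raw p-values are always
    reported.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("need at least 3 profiles per group")
    profiles = list(group_a) + list(group_b)
    widths = {round(float(np.diff(p.bin_edges_um)[0]), 9) for p in profiles}
    starts = {float(p.bin_edges_um[0]) for p in profiles}
    if len(widths) > 1 or len(starts) > 1:
        raise ValueError("profiles must share a bin grid")
    n_bins = max(p.stained_area_per_bin_um2.size for p in profiles)
    width = widths.pop()
    edges = starts.pop() + np.arange(n_bins + 1) * width

    def padded(p: DepthProfile) -> np.ndarray:
        v = np.zeros(n_bins)
        v[: p.stained_area_per_bin_um2.size] = p.stained_area_per_bin_um2
        return v

    mat_a = np.array([padded(p) for p in group_a])
    mat_b = np.array([padded(p) for p in group_b])
    p_vals = np.array(
        [_mannwhitney_bin(mat_a[:, j], mat_b[:, j]) for j in range(n_bins)]
    )
    adjusted = None
    if adjust is not None:
        if adjust != "bh":
            raise ValueError("only Benjamini-Hochberg ('bh') adjustment is offered")
        from statsmodels.stats.multitest import multipletests

        adjusted = multipletests(p_vals, method="fdr_bh")[1]
    return CurveComparison(
        bin_edges_um=edges,
        p_per_bin=p_vals,
        adjusted_p_per_bin=adjusted,
        method="mann-whitney",
    )


def kruskal_dunn(
    groups: Sequence[Sequence[float]],
    adjust: str = "bonferroni",
) -> Dict[str, object]:
    """Kruskal-Wallis H test with Dunn's pairwise post-hoc comparisons.

    Dunn's test compares mean ranks of the pooled sample; the z
    statistic for groups i, j uses the tie-corrected pooled-rank
    variance. Pairwise p-values are adjusted for the k*(k-1)/2
    comparisons (Bonferroni by default, "holm" or "none" otherwise).

    Returns a dict with ``H``, ``p`` (omnibus) and ``dunn_p`` — a
    symmetric k x k DataFrame of adjusted pairwise p-values.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        h_stat, p_omni = 0.0, 1.0
    else:
        h_stat, p_omni = sps.kruskal(*groups)

    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    sizes = [g.size for g in groups]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[offsets[i] : offsets[i + 1]].mean() for i in range(len(groups))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0
    tie_corr = tie_term / (12.0 * (n_total - 1)) if n_total > 1 else 0.0

    k = len(groups)
    pmat = np.ones((k, k))
    m = k * (k - 1) // 2
    raw = {}
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt((base_var - tie_corr) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            p_ij = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_ij = 2.0 * sps.norm.sf(abs(z))
        raw[(i, j)] = p_ij
    if adjust == "bonferroni":
        adj = {k_: min(v * m, 1.0) for k_, v in raw.items()}
    elif adjust == "holm":
        items = sorted(raw.items(), key=lambda kv: kv[1])
        adj = {}
        running = 0.0
        for rank, (key, v) in enumerate(items):
            val = min((m - rank) * v, 1.0)
            running = max(running, val)
            adj[key] = running
    elif adjust == "none":
        adj = raw
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    for (i, j), v in adj.items():
        pmat[i, j] = pmat[j, i] = v
    labels = [f"group{i + 1}" for i in range(k)]
    return {
        "H": float(h_stat),
        "p": float(p_omni),
        "dunn_p": pd.DataFrame(pmat, index=labels, columns=labels),
        "adjustment": adjust,
    }


def two_way_anova_tukey(
    values: Sequence[float],
    factor_limb: Sequence[str],
    factor_group: Sequence[int],
) -> Dict[str, object]:
    """Two-way ANOVA (limb x group) with Tukey HSD pairwise comparisons.

    Fits ``value ~ limb * group`` by ordinary least squares and reports
    the type-II ANOVA table plus Tukey HSD comparisons between the
    limb-by-group cells. Every cell needs at least two observations.
    Data with (numerically) zero total variance are degenerate for an
    F test; that case returns F = 0, p = 1 with ``degenerate=True``.
    Zero residual variance with real effects is flagged the same way.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "limb": list(factor_limb),
            "group": [str(g) for g in factor_group],
        }
    )
    cells = df.groupby(["limb", "group"], sort=True).size()
    expected = {(l, g) for l in df["limb"].unique() for g in df["group"].unique()}
    for cell in sorted(expected):
        if cell not in cells.index or cells.loc[cell] < 2:
            raise ValueError(
                f"cell limb={cell[0]}, group={cell[1]} has fewer than 2 observations"
            )

    factors = ["limb", "group", "limb:group"]
    total_var = float(df["value"].var(ddof=0))
    scale = max(abs(df["value"]).max(), 1.0)
    if total_var <= (1e-12 * scale) ** 2:
        table = pd.DataFrame(
            {"F": [0.0] * 3, "p": [1.0] * 3}, index=factors
        )
        return {"anova": table, "tukey": None, "degenerate": True}

    model = ols("value ~ C(limb) * C(group)", data=df).fit()
    if model.ssr <= 1e-10 * float(df["value"].var(ddof=0)) * len(df):
        # perfect fit: zero error mean square, F is unbounded
        table = pd.DataFrame(
            {"F": [np.inf] * 3, "p": [np.nan] * 3}, index=factors
        )
        return {"anova": table, "tukey": None, "degenerate": True}
    anova = sm.stats.anova_lm(model, typ=2)
    table = pd.DataFrame(
        {
            "F": [
                anova.loc["C(limb)", "F"],
                anova.loc["C(group)", "F"],
                anova.loc["C(limb):C(group)", "F"],
            ],
            "p": [
                anova.loc["C(limb)", "PR(>F)"],
                anova.loc["C(group)", "PR(>F)"],
                anova.loc["C(limb):C(group)", "PR(>F)"],
            ],
        },
        index=factors,
    )
    degenerate = not np.isfinite(table["F"]).all()
    if degenerate:
        return {"anova": table, "tukey": None, "degenerate": True}
    cell_label = df["limb"] + "/" + df["group"]
    tukey = pairwise_tukeyhsd(df["value"].to_numpy(), cell_label.to_numpy())
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {"anova": table, "tukey": tukey_df, "degenerate": False}


def spearman(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Spearman rank correlation: rho, rho^2 and two-sided p.

    Both rho and rho^2 are reported — a bare "r^2" is ambiguous about
    sign. Constant input has no rank ordering; the result is flagged
    undefined (NaNs) rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"rho": float("nan"), "rho2": float("nan"), "p": float("nan"),
                "defined": False}
    rho, p = sps.spearmanr(x, y)
    return {"rho": float(rho), "rho2": float(rho) ** 2, "p": float(p),
            "defined": True}
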