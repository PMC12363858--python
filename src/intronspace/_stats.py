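"""Rank-based group comparisons: Mann-Whitney, Kruskal-Wallis + Dunn/BH.

Dunn's post hoc test is the standard all-pairs follow-up to Kruskal-Wallis:
groups are ranked jointly, and each pair (i, j) is compared with

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j))

where T = sum(t^3 - t) / (12 (N - 1)) corrects for ties.  Two-sided normal
p-values are Benjamini-Hochberg adjusted across pairs.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def dunn_test(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """All-pairs Dunn z tests with tie correction and BH adjustment.

    Returns one row per pair: group1, group2, z, p_raw, p_adjusted.
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name, v in zip(names, values):
        mean_ranks[name] = ranks[start : start + len(v)].mean()
        start += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for g1, g2 in combinations(names, 2):
        n1, n2 = len(groups[g1]), len(groups[g2])
        se = np.sqrt(var_base * (1.0 / n1 + 1.0 / n2))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[g1] - mean_ranks[g2]) / se
            p = 2 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(df["p_raw"].to_numpy(), method="fdr_bh")
    df["p_adjusted"] = np.maximum(p_adj, df["p_raw"])
    return df


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact for small untied samples."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if np.array_equal(np.sort(x), np.sort(y)):
        return float(len(x) * len(y) / 2), 1.0
    # exact rank enumeration for small samples without cross-group ties
    cross_ties = len(np.intersect1d(x, y)) > 0
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not cross_ties) else "auto"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    if all(np.array_equal(np.sort(values[0]), np.sort(v)) for v in values[1:]):
        return 0.0, 1.0
    h, p = stats.kruskal(*values)
    return float(h), float(p)
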