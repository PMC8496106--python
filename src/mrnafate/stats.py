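"""Thin nonparametric group-comparison utilities.

Kruskal-Wallis across groups, Dunn's z-tests for the pairwise follow-up,
and Benjamini-Hochberg adjustment, with the significance-star convention
used throughout this pipeline's figures (*** p.adj < 0.001, ** < 0.01,
* < 0.1).
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def significance_stars(p_adj: float) -> str:
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.1:
        return "*"
    return "ns"


def kruskal_dunn(groups: Mapping[str, Sequence[float]]) -> tuple[float, pd.DataFrame]:
    """Kruskal-Wallis p plus BH-adjusted Dunn pairwise comparisons.

    Dunn's z uses pooled mid-ranks with the standard tie correction.
    Returns the overall Kruskal-Wallis p-value and a table with one row
    per group pair (z, p, p_adj, stars).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(groups[g], dtype=float) for g in names}
    kw_p = float(stats.kruskal(*arrays.values()).pvalue)

    pooled = np.concatenate([arrays[g] for g in names])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1)))

    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    start = 0
    for g in names:
        m = len(arrays[g])
        mean_ranks[g] = float(ranks[start : start + m].mean())
        sizes[g] = m
        start += m

    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p": float(p)})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    table["stars"] = table["p_adj"].map(significance_stars)
    return kw_p, table
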