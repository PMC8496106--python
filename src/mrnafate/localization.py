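"""Spike-in-anchored normalization, k-means clustering, and set enrichment.

Subcellular fractionation counts are made comparable across fractions by
equalizing ERCC spike-in totals (the spike-ins were dosed proportionally,
so their totals track absolute RNA recovered per fraction), then scaled
to counts per million. Clustering uses plain k-means with many restarts;
the number of clusters is either fixed (two for ER vs cytosol) or chosen
at the elbow of the within-cluster sum-of-squares curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .core_io import CountTable, InputError


def ercc_scale(table: CountTable, spike_ids: Sequence[str]) -> CountTable:
    """Rescale each sample so spike-in totals match the first sample's total.

    After scaling, every column's spike-in total equals the reference, so
    transcript counts are on a common absolute scale. Idempotent.
    """
    spikes = [s for s in spike_ids if s in table.values.index]
    if not spikes:
        raise InputError("no spike-in rows found in the table")
    totals = table.values.loc[spikes].sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise InputError(f"zero spike-in total in columns: {bad}")
    reference = float(totals.iloc[0])
    scaled = table.values * (reference / totals)
    return CountTable(values=scaled, samples=table.samples.copy())


def cpm(values: pd.DataFrame) -> pd.DataFrame:
    """Counts per million per column."""
    totals = values.sum(axis=0)
    if (totals == 0).any():
        raise InputError(f"zero column total: {list(totals.index[totals == 0])}")
    return values * 1e6 / totals


@dataclass
class ClusterAssignment:
    labels: pd.Series  # transcript id -> cluster label in 1..k
    k: int
    wss_curve: dict[int, float]  # k -> within-cluster sum of squares


def _transform(matrix: pd.DataFrame, transform: str) -> pd.DataFrame:
    if transform == "log2p1":
        return np.log2(matrix + 1.0)
    if transform == "log":
        if (matrix <= 0).any().any():
            raise InputError("log transform requires strictly positive values")
        return np.log(matrix)
    if transform == "none":
        return matrix
    raise InputError(f"unknown transform {transform!r}")


def kmeans_cluster(
    matrix: pd.DataFrame,
    k: int | str = "auto",
    transform: str = "none",
    seed: int = 0,
    n_init: int = 25,
    k_max: int = 10,
) -> ClusterAssignment:
    """k-means with deterministic label ordering by cluster mean.

    ``k="auto"`` picks the elbow of the WSS curve (largest second
    difference) over k = 1..k_max. Cluster labels are renumbered 1..k in
    ascending order of the cluster's mean feature value, so labels do not
    depend on initialization order.
    """
    X = _transform(matrix, transform).to_numpy(dtype=float)
    if np.isnan(X).any():
        raise InputError("missing values after transform")
    n = len(X)
    wss_curve: dict[int, float] = {1: float(((X - X.mean(axis=0)) ** 2).sum())}
    models: dict[int, KMeans] = {}
    k_upper = min(k_max, n) if k == "auto" else int(k)
    if k != "auto" and k_upper > n:
        raise InputError(f"k={k_upper} exceeds {n} rows")
    if k != "auto" and k_upper < 2:
        raise InputError("k must be >= 2")
    for kk in range(2, (k_upper if k == "auto" else k_upper) + 1):
        m = KMeans(n_clusters=kk, n_init=n_init, random_state=seed).fit(X)
        models[kk] = m
        wss_curve[kk] = float(m.inertia_)
    if k == "auto":
        ks = sorted(wss_curve)
        if len(ks) < 3:
            best_k = ks[-1]
        else:
            # elbow on log(WSS): the raw curve's first drop dominates raw
            # second differences and would always select k = 2
            logw = {kk: np.log(max(wss_curve[kk], 1e-300)) for kk in ks}
            second_diff = {
                ks[i]: logw[ks[i - 1]] - 2 * logw[ks[i]] + logw[ks[i + 1]]
                for i in range(1, len(ks) - 1)
            }
            best_k = max(second_diff, key=lambda kk: (second_diff[kk], -kk))
    else:
        best_k = k_upper
    model = models[best_k]
    raw = model.labels_
    order = np.argsort(model.cluster_centers_.mean(axis=1))
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = pd.Series([relabel[int(v)] for v in raw], index=matrix.index, name="cluster")
    return ClusterAssignment(labels=labels, k=best_k, wss_curve=wss_curve)


def group_enrichment(
    membership_a: Iterable[str], membership_b: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """Overlap of two transcript sets: Haldane-corrected odds ratio, Fisher p.

    The two-sided Fisher exact p-value comes from the uncorrected 2x2
    table; the odds ratio adds 0.5 to every cell so it stays finite.
    """
    uni = set(universe)
    if not uni:
        raise InputError("empty universe")
    a = set(membership_a) & uni
    b = set(membership_b) & uni
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(uni) - n11 - n10 - n01
    _, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    odds = ((n11 + 0.5) * (n00 + 0.5)) / ((n10 + 0.5) * (n01 + 0.5))
    return float(odds), float(p)
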