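"""Ward hierarchical clustering along depth and rainfall gradients.

Clustering runs on *unscaled* data on purpose: depth (0-100 cm) and
rainfall (306-1493 mm) dominate the Euclidean distances numerically, so the
tree organises the horizons primarily along the chosen gradient without any
weighting step.  The agglomerator is Ward's minimum-variance method on
squared Euclidean distances: at each step the merge that least increases
total within-cluster variance is taken, with merge costs maintained by the
Lance-Williams recurrence and ties broken by the lowest cluster-id pair so
results are deterministic for a given row order.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .columns import PIT_COLUMN

__all__ = [
    "WardTree",
    "ward_linkage",
    "ward_cluster",
    "within_cluster_variance",
    "summarize_clusters",
    "cluster_depth_profile",
    "cluster_rainfall_surface",
    "DEPTH_CLUSTER_VARS",
    "RAINFALL_CLUSTER_VARS",
]

#: carbon responses + final-model predictors clustered along depth
DEPTH_CLUSTER_VARS = [
    "SOC", "k2", "k1",
    "CEC", "WS_agg", "Fe_p/Al_p", "Roots",
    "Fe_c/Al_c", "Si_p/Al_p", "Clay", "AEC",
]

#: the same set for surface soils, clustered along rainfall
RAINFALL_CLUSTER_VARS = DEPTH_CLUSTER_VARS


@dataclass
class WardTree:
    """Merge sequence of a Ward agglomeration.

    ``merges[m] = (i, j, cost, size)``: at step m clusters ``i`` and ``j``
    (ids < n are original rows; id n+m is the new cluster) merge at
    within-cluster variance increase ``cost`` into a cluster of ``size``
    rows.
    """

    n: int
    merges: list[tuple[int, int, float, int]]

    def cut(self, k: int) -> np.ndarray:
        """Labels (0..k-1) after stopping at k clusters.

        Cutting at k then k-1 merges exactly two of the k clusters (the
        nesting property of agglomerative trees).  Labels are assigned in
        order of each cluster's smallest original row index.
        """
        if k < 1 or k > self.n:
            raise ValueError(f"k must be in [1, {self.n}]")
        members: dict[int, list[int]] = {i: [i] for i in range(self.n)}
        for m, (i, j, _, _) in enumerate(self.merges[: self.n - k]):
            members[self.n + m] = members.pop(i) + members.pop(j)
        clusters = sorted(members.values(), key=min)
        labels = np.empty(self.n, dtype=int)
        for lab, rows in enumerate(clusters):
            labels[rows] = lab
        return labels


def ward_linkage(X: np.ndarray) -> WardTree:
    """Greedy Ward agglomeration of the rows of ``X``.

    The cost of merging clusters A, B is the increase in total
    within-cluster sum of squares,
    ``|A||B|/(|A|+|B|) * ||mean(A) - mean(B)||^2``; costs after a merge are
    updated with the Lance-Williams recurrence.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a 2-D row matrix")
    if np.any(~np.isfinite(X)):
        raise ValueError("X contains missing or non-finite values")
    n = X.shape[0]
    # merge costs between singletons: ||xi - xj||^2 / 2
    sq = np.sum(X ** 2, axis=1)
    d = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0) / 2.0
    np.fill_diagonal(d, np.inf)

    active: dict[int, int] = {i: i for i in range(n)}   # cluster id -> slot
    size = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    for m in range(n - 1):
        ids = sorted(active)
        slots = np.array([active[c] for c in ids])
        sub = d[np.ix_(slots, slots)]
        iu = np.triu_indices(len(ids), k=1)
        costs = sub[iu]
        # ties broken by the lowest (i, j) cluster-id pair: iu enumerates
        # pairs in id-lexicographic order and argmin takes the first
        best = int(np.argmin(costs))
        cost = float(costs[best])
        ci, cj = ids[iu[0][best]], ids[iu[1][best]]
        si, sj = active[ci], active[cj]
        ni, nj = size[ci], size[cj]
        new_id = n + m
        # Lance-Williams update of merge costs into the surviving slot si
        for ck in ids:
            if ck in (ci, cj):
                continue
            sk = active[ck]
            nk = size[ck]
            d[si, sk] = d[sk, si] = (
                (ni + nk) * d[si, sk] + (nj + nk) * d[sj, sk]
                - nk * cost
            ) / (ni + nj + nk)
        d[sj, :] = np.inf
        d[:, sj] = np.inf
        del active[ci], active[cj], size[ci], size[cj]
        active[new_id] = si
        size[new_id] = ni + nj
        merges.append((ci, cj, float(cost), ni + nj))
    return WardTree(n=n, merges=merges)


def ward_cluster(X: np.ndarray, k: int) -> np.ndarray:
    """Cluster rows of ``X`` into ``k`` groups by Ward's method."""
    X = np.asarray(X, dtype=float)
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of rows")
    return ward_linkage(X).cut(k)


def within_cluster_variance(X: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squares for a labelling."""
    X = np.asarray(X, dtype=float)
    total = 0.0
    for lab in np.unique(labels):
        rows = X[labels == lab]
        total += float(np.sum((rows - rows.mean(axis=0)) ** 2))
    return total


def summarize_clusters(table: pd.DataFrame, labels: np.ndarray,
                       variables: list[str], order_by: str) -> pd.DataFrame:
    """Per-cluster medians, quartiles and notched-boxplot median CIs.

    The 95% CI of the median uses the boxplot-notch half-width
    ``1.58 * IQR / sqrt(n)``.  Clusters are renumbered in increasing order
    of their median ``order_by`` value.
    """
    work = table.copy()
    work["_label"] = labels
    order = (work.groupby("_label")[order_by].median()
             .sort_values(kind="mergesort").index)
    rows = []
    for rank, lab in enumerate(order):
        grp = work[work["_label"] == lab]
        n = len(grp)
        for var in variables:
            x = grp[var].dropna()
            med = x.median()
            q1, q3 = x.quantile(0.25), x.quantile(0.75)
            half = 1.58 * (q3 - q1) / np.sqrt(max(len(x), 1))
            rows.append({
                "cluster": rank, "n": n, "variable": var,
                "median": med, "q1": q1, "q3": q3,
                "ci_lo": med - half, "ci_hi": med + half,
                f"median_{order_by.lower()}": grp[order_by].median(),
            })
    return pd.DataFrame(rows)


def cluster_depth_profile(table: pd.DataFrame,
                          variables: list[str] | None = None,
                          k: int = 5) -> tuple[np.ndarray, pd.DataFrame]:
    """Ward clustering of all horizons on unscaled responses, predictors
    and depth; five clusters by default (additional clusters reduce the
    within-cluster variance little).  Clusters are reported shallow to
    deep."""
    variables = DEPTH_CLUSTER_VARS if variables is None else list(variables)
    cols = [v for v in variables if v != "Depth"] + ["Depth"]
    rows = table.dropna(subset=cols)
    labels = ward_cluster(rows[cols].to_numpy(dtype=float), k)
    summary = summarize_clusters(rows, labels, cols, order_by="Depth")
    return labels, summary


def cluster_rainfall_surface(table: pd.DataFrame,
                             variables: list[str] | None = None,
                             k: int = 3) -> tuple[np.ndarray, pd.DataFrame]:
    """Ward clustering of surface horizons (shallowest per pit) with the
    pit's rainfall added; three clusters by default, reported dry to wet."""
    variables = RAINFALL_CLUSTER_VARS if variables is None else list(variables)
    surface = (table.sort_values("Depth")
               .groupby(PIT_COLUMN, sort=False).head(1))
    cols = [v for v in variables if v != "Rainfall"] + ["Rainfall"]
    rows = surface.dropna(subset=cols)
    if len(rows) < k:
        raise ValueError("fewer surface rows than clusters requested")
    labels = ward_cluster(rows[cols].to_numpy(dtype=float), k)
    summary = summarize_clusters(rows, labels, cols, order_by="Rainfall")
    return labels, summary
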