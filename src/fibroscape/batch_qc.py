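"""Batch-effect detection via k-nearest-neighbour overlap z-scores.

For a candidate confounding grouping (patient, dataset), the observed
statistic for each cell of a group is the number of its k nearest
neighbours that fall in the same group (nOverlap). The null distribution is
built by drawing random cell subsets of matched size and computing the same
per-cell overlap against the drawn set; z-scores are
``(nOverlap - mean_null) / sd_null`` and a group is flagged when its median
z exceeds a threshold (1.96 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CellMatrix

__all__ = ["NeighborGraph", "BatchReport", "build_neighbor_graph", "knn_overlap_zscores"]


@dataclass
class NeighborGraph:
    """Per-cell ordered k nearest neighbours (self excluded)."""

    indices: np.ndarray  # (n_cells, k) int
    k: int
    embedding: str = "pca"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        n, k = self.indices.shape
        if k != self.k:
            raise ValueError("indices width does not match k")
        if (self.indices < 0).any() or (self.indices >= n).any():
            raise ValueError("neighbour index out of range")
        if (self.indices == np.arange(n)[:, None]).any():
            raise ValueError("self-loop in neighbour graph")

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]


@dataclass
class BatchReport:
    """Per-group kNN-overlap z summary plus the per-cell z-scores."""

    groups: pd.DataFrame  # group_id, n_cells, median_z, flagged
    cell_z: pd.Series  # per-cell z, indexed like the input labels
    n_random: int
    z_threshold: float
    seed: int

    @property
    def flagged_fraction(self) -> float:
        return float(self.groups["flagged"].mean())

    def to_csv(self, path) -> None:
        self.groups.to_csv(path, index=False)


def build_neighbor_graph(
    expr: CellMatrix, k: int = 20, n_pcs: int = 30, seed: int = 0
) -> NeighborGraph:
    """kNN graph on the top principal components of log-normalized data."""
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    X = expr.lognorm.T  # cells x genes
    n_pcs = min(n_pcs, X.shape[0] - 1, X.shape[1])
    emb = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    return NeighborGraph(indices=idx[:, 1:], k=k, embedding=f"pca{n_pcs}")


def knn_overlap_zscores(
    graph: NeighborGraph,
    groups: pd.Series | np.ndarray,
    n_random: int = 1000,
    z_threshold: float = 1.96,
    seed: int = 0,
    exhaustive: bool = False,
) -> BatchReport:
    """kNN-overlap z-scores per group with a matched random-subset null.

    For each group g of size m, the observed per-cell overlaps are
    ``o_i = |neighbours(i) ∩ g|`` for i in g. The null pools per-cell
    overlaps from ``n_random`` uniform draws of m cells (without
    replacement within each draw), computed the same way against the drawn
    set. ``z_i = (o_i - mean_null) / sd_null``; the group is flagged when
    ``median(z_i) > z_threshold``.
    """
    labels = pd.Series(np.asarray(groups))
    n = graph.n_cells
    if len(labels) != n:
        raise ValueError("group labels length does not match graph")
    uniq = labels.unique()
    if len(uniq) < 2:
        warnings.warn("fewer than 2 groups; overlap is degenerate (z undefined)", stacklevel=2)
    rng = np.random.default_rng(seed)

    rows = []
    cell_z = np.full(n, np.nan)
    for g in uniq:
        members = np.flatnonzero(labels.to_numpy() == g)
        m = members.size
        if m < graph.k + 1:
            raise ValueError(f"group {g!r} has {m} cells; need >= k+1 = {graph.k + 1}")
        in_g = np.zeros(n, dtype=bool)
        in_g[members] = True
        observed = in_g[graph.indices[members]].sum(axis=1)

        if exhaustive:
            # enumerate every m-subset (tiny graphs only)
            from itertools import combinations
            from math import comb

            if comb(n, m) > 100_000:
                raise ValueError("exhaustive null infeasible for this size")
            draws = [np.array(c) for c in combinations(range(n), m)]
        else:
            draws = [rng.choice(n, size=m, replace=False) for _ in range(n_random)]
        null_overlaps = np.empty((len(draws), m), dtype=np.int64)
        for r, draw in enumerate(draws):
            in_s = np.zeros(n, dtype=bool)
            in_s[draw] = True
            null_overlaps[r] = in_s[graph.indices[draw]].sum(axis=1)
        mean_null = null_overlaps.mean()
        sd_null = null_overlaps.std(ddof=0)

        if sd_null == 0:
            warnings.warn(
                f"group {g!r}: null overlap sd is 0; z undefined, not flagged",
                stacklevel=2,
            )
            median_z = np.nan
            flagged = False
        else:
            z = (observed - mean_null) / sd_null
            cell_z[members] = z
            median_z = float(np.median(z))
            flagged = median_z > z_threshold
        rows.append(
            {"group_id": g, "n_cells": int(m), "median_z": median_z, "flagged": flagged}
        )

    report = pd.DataFrame(rows)
    return BatchReport(
        groups=report,
        cell_z=pd.Series(cell_z, name="knn_overlap_z"),
        n_random=n_random,
        z_threshold=z_threshold,
        seed=seed,
    )
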