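"""Sample-level marker statistics and the clustering-resolution sweep.

Marker claims made from single-cell tests alone treat cells as independent
replicates and are inflated by within-patient correlation. The approach
here first averages log-normalized expression per (sample, cluster) pseudo
sample, then tests markers across samples: a gene is a supported marker of
a cluster only when the sample-level average log2 fold change exceeds 1,
the Bonferroni-adjusted p is below 0.01 and at least half of the samples
express it. The resolution sweep uses this criterion to pick the finest
clustering whose every cluster still has supported markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .batch_qc import NeighborGraph
from .containers import CellMatrix

__all__ = [
    "pseudo_sample_profiles",
    "sample_level_markers",
    "resolution_sweep",
    "snn_leiden",
    "ResolutionSweepResult",
]

_LFC_PSEUDOCOUNT = 1.0  # on expm1 of profile values, Seurat-style


def pseudo_sample_profiles(
    expr: CellMatrix,
    clusters: pd.Series | np.ndarray,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Mean log-normalized expression per (sample, cluster) pseudo sample.

    Returns genes x (sample, cluster) with MultiIndex columns; pairs with
    fewer than ``min_cells`` cells are dropped with a warning. Per-column
    cell counts are stored in ``.attrs['n_cells']``.
    """
    clu = np.asarray(clusters)
    if len(clu) != expr.n_cells:
        raise ValueError("cluster labels length does not match matrix")
    if len(clu) == 0 or pd.isna(clu).all():
        raise ValueError("empty clustering")
    samples = np.asarray(expr.cell_meta["sample_id"])
    X = expr.lognorm

    lin = np.expm1(X)
    cols: dict[tuple, np.ndarray] = {}
    lin_cols: dict[tuple, np.ndarray] = {}
    n_cells: dict[tuple, int] = {}
    dropped = 0
    for s in pd.unique(samples):
        for c in pd.unique(clu):
            mask = (samples == s) & (clu == c)
            m = int(mask.sum())
            if m == 0:
                continue
            if m < min_cells:
                dropped += 1
                continue
            cols[(s, c)] = X[:, mask].mean(axis=1)
            lin_cols[(s, c)] = lin[:, mask].mean(axis=1)
            n_cells[(s, c)] = m
    if dropped:
        warnings.warn(f"dropped {dropped} (sample, cluster) pairs with < {min_cells} cells",
                      stacklevel=2)
    if not cols:
        raise ValueError("no (sample, cluster) pair satisfies min_cells")
    prof = pd.DataFrame(cols, index=pd.Index(expr.genes, name="gene"))
    prof.columns = pd.MultiIndex.from_tuples(prof.columns, names=["sample_id", "cluster"])
    linear = pd.DataFrame(lin_cols, index=prof.index)
    linear.columns = prof.columns
    prof.attrs["n_cells"] = n_cells
    # arithmetic means on the linear scale back the fold-change estimate;
    # averaging log values instead (a geometric mean) understates how much
    # a mixed rest group dilutes a marker
    prof.attrs["linear"] = linear
    return prof


def _profile_lfc(lin_target: np.ndarray, lin_rest: np.ndarray) -> np.ndarray:
    """Sample-level average log2 fold change from linear-scale sample means."""
    a = np.log2(lin_target + _LFC_PSEUDOCOUNT)
    b = np.log2(lin_rest + _LFC_PSEUDOCOUNT)
    return (a - b).mean(axis=1)


def _linear_layer(prof: pd.DataFrame) -> pd.DataFrame:
    return prof.attrs.get("linear", np.expm1(prof))


def _rest_profile(layer: pd.DataFrame, n_cells: dict, sample: str, cluster) -> np.ndarray | None:
    """Cell-count-weighted mean profile over the sample's other clusters."""
    others = [c for (s, c) in layer.columns if s == sample and c != cluster]
    if not others:
        return None
    w = np.array([n_cells[(sample, c)] for c in others], dtype=float)
    block = layer.loc[:, [(sample, c) for c in others]].to_numpy()
    return block @ (w / w.sum())


def sample_level_markers(
    profiles: pd.DataFrame,
    contrast,
    min_lfc: float = 1.0,
    alpha: float = 0.01,
    min_frac: float = 0.5,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-gene sample-level marker statistics for one contrast.

    ``contrast`` is either ``("cluster", c)`` — cluster c versus the
    weighted rest of each sample — or
    ``("group", mask_a, mask_b)`` with boolean masks over profile columns
    for an A-vs-B comparison (e.g. tumour vs control sample sets). The test
    across sample profiles is the exact Mann-Whitney by default; set
    ``paired=True`` for the Wilcoxon signed-rank across paired columns
    (note its exact p is floored at ``2**-(n-1)``, so with few samples it
    cannot survive a genome-wide Bonferroni correction). p-values are
    Bonferroni-adjusted over tested genes; the
    ``passes`` flag applies the marker criterion
    ``sample_log2fc > min_lfc and adj_p < alpha and
    frac_samples_expressing >= min_frac``.
    """
    genes = profiles.index
    linear = _linear_layer(profiles)
    if contrast[0] == "cluster":
        cluster = contrast[1]
        n_cells = profiles.attrs.get(
            "n_cells", {c: 1 for c in profiles.columns}
        )
        tgt_cols, rest, lin_tgt, lin_rest = [], [], [], []
        for (s, c) in profiles.columns:
            if c != cluster:
                continue
            r = _rest_profile(profiles, n_cells, s, cluster)
            if r is None:
                continue
            tgt_cols.append(profiles[(s, c)].to_numpy())
            rest.append(r)
            lin_tgt.append(linear[(s, c)].to_numpy())
            lin_rest.append(_rest_profile(linear, n_cells, s, cluster))
        if len(tgt_cols) < 3:
            raise ValueError(
                f"contrast cluster {cluster!r}: only {len(tgt_cols)} paired samples (need >= 3)"
            )
        A = np.column_stack(tgt_cols)
        B = np.column_stack(rest)
        p = _paired_wilcoxon(A, B) if paired else _exact_ranksum(A, B)
        lfc = _profile_lfc(np.column_stack(lin_tgt), np.column_stack(lin_rest))
        frac = (A > 0).mean(axis=1)
        label = cluster
    elif contrast[0] == "group":
        _, mask_a, mask_b = contrast
        A = profiles.loc[:, np.asarray(mask_a)].to_numpy()
        B = profiles.loc[:, np.asarray(mask_b)].to_numpy()
        La = linear.loc[:, np.asarray(mask_a)].to_numpy()
        Lb = linear.loc[:, np.asarray(mask_b)].to_numpy()
        if A.shape[1] < 3 or B.shape[1] < 3:
            raise ValueError("group contrast: need >= 3 samples per side")
        if paired:
            if A.shape[1] != B.shape[1]:
                raise ValueError("paired group contrast requires equal-length sides")
            p = _paired_wilcoxon(A, B)
        else:
            p = _exact_ranksum(A, B)
        lfc = _profile_lfc(La, Lb) if paired else _profile_lfc_unpaired(La, Lb)
        frac = (A > 0).mean(axis=1)
        label = "groupA"
    else:
        raise ValueError(f"unknown contrast kind {contrast[0]!r}")

    adj_p = np.minimum(1.0, p * len(genes))
    out = pd.DataFrame(
        {
            "gene": genes,
            "cluster": label,
            "sample_log2fc": lfc,
            "p": p,
            "adj_p": adj_p,
            "frac_samples_expressing": frac,
        }
    )
    out["passes"] = (
        (out["sample_log2fc"] > min_lfc)
        & (out["adj_p"] < alpha)
        & (out["frac_samples_expressing"] >= min_frac)
    )
    return out.reset_index(drop=True)


def _profile_lfc_unpaired(La: np.ndarray, Lb: np.ndarray) -> np.ndarray:
    a = np.log2(La + _LFC_PSEUDOCOUNT).mean(axis=1)
    b = np.log2(Lb + _LFC_PSEUDOCOUNT).mean(axis=1)
    return a - b


def _exact_ranksum(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Mann-Whitney p, exact null at sample-profile sizes.

    With tens of sample profiles per side, the normal approximation floors
    the attainable p-value too high to survive a Bonferroni correction over
    thousands of genes; the exact null does not.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(A, B, axis=1, method="exact")
    return np.atleast_1d(res.pvalue)


def _paired_wilcoxon(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Wilcoxon signed-rank p; all-zero difference rows give p = 1."""
    diffs = A - B
    p = np.ones(A.shape[0])
    nz = (diffs != 0).any(axis=1)
    if nz.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(
                diffs[nz], axis=1, zero_method="wilcox", method="auto"
            )
        p[nz] = np.atleast_1d(res.pvalue)
    return p


# ----------------------------------------------------------------------
# clustering-resolution sweep
# ----------------------------------------------------------------------
def snn_leiden(
    graph: NeighborGraph, resolution: float, seed: int = 0, prune: float = 1 / 15
) -> np.ndarray:
    """Shared-nearest-neighbour graph + Leiden modularity clustering.

    Edges are weighted by the Jaccard overlap of neighbour lists and pruned
    below ``prune``; community detection maximizes RB-configuration
    modularity at the given resolution with a fixed seed. Cluster indices
    are relabelled by decreasing size.
    """
    import igraph as ig
    import leidenalg

    n, k = graph.indices.shape
    neigh = [set(graph.indices[i]) | {i} for i in range(n)]
    pairs = {
        (min(i, int(j)), max(i, int(j)))
        for i in range(n)
        for j in graph.indices[i]
    }
    edges, weights = [], []
    for i, j in sorted(pairs):
        jac = len(neigh[i] & neigh[j]) / len(neigh[i] | neigh[j])
        if jac >= prune:
            edges.append((i, j))
            weights.append(jac)
    g = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    memb = np.asarray(part.membership)
    # stable relabelling: by decreasing size, ties by lowest original index
    sizes = pd.Series(memb).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {c: i for i, c in enumerate(order)}
    return np.array([remap[c] for c in memb])


@dataclass
class ResolutionSweepResult:
    """Outcome of the marker-supported resolution sweep."""

    table: pd.DataFrame  # resolution, n_clusters, min_markers, all_clusters_supported
    chosen_resolution: float | None
    clusters_at_chosen: np.ndarray | None
    markers_at_chosen: pd.DataFrame | None

    @property
    def n_clusters_chosen(self) -> int | None:
        if self.clusters_at_chosen is None:
            return None
        return int(len(np.unique(self.clusters_at_chosen)))


def resolution_sweep(
    expr: CellMatrix,
    graph: NeighborGraph,
    resolutions,
    marker_min: int = 1,
    min_lfc: float = 1.0,
    alpha: float = 0.01,
    min_frac: float = 0.5,
    min_cells: int = 3,
    paired: bool = False,
    seed: int = 0,
) -> ResolutionSweepResult:
    """Find the finest clustering in which every cluster keeps markers.

    For each resolution (ascending), the SNN graph is partitioned, markers
    per cluster are computed with :func:`sample_level_markers` and a
    resolution is *supported* when every cluster has at least
    ``marker_min`` passing markers. The chosen resolution is the largest
    supported one.
    """
    resolutions = list(resolutions)
    if resolutions != sorted(resolutions):
        raise ValueError("resolutions must be sorted ascending")
    rows = []
    chosen = None
    chosen_clusters = None
    chosen_markers = None
    for res in resolutions:
        memb = snn_leiden(graph, resolution=res, seed=seed)
        n_clusters = len(np.unique(memb))
        per_cluster = []
        marker_tables = []
        try:
            profiles = pseudo_sample_profiles(expr, memb, min_cells=min_cells)
            for c in np.unique(memb):
                tab = sample_level_markers(
                    profiles, ("cluster", c), min_lfc=min_lfc, alpha=alpha,
                    min_frac=min_frac, paired=paired,
                )
                per_cluster.append(int(tab["passes"].sum()))
                marker_tables.append(tab)
        except ValueError:
            # single-cluster solutions have no rest to contrast against:
            # treated as trivially supported
            per_cluster = [marker_min] if n_clusters == 1 else [0]
            marker_tables = []
        supported = all(m >= marker_min for m in per_cluster)
        rows.append(
            {
                "resolution": res,
                "n_clusters": n_clusters,
                "min_markers_per_cluster": min(per_cluster),
                "all_clusters_supported": supported,
            }
        )
        if supported:
            chosen = res
            chosen_clusters = memb
            chosen_markers = (
                pd.concat(marker_tables, ignore_index=True) if marker_tables else None
            )
    return ResolutionSweepResult(
        table=pd.DataFrame(rows),
        chosen_resolution=chosen,
        clusters_at_chosen=chosen_clusters,
        markers_at_chosen=chosen_markers,
    )
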