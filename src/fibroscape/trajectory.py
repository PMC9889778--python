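"""Diffusion pseudotime trajectory analysis and cross-dataset meta-analysis.

Pipeline: (1) diffusion-map embedding of log-normalized expression with a
locally adaptive Gaussian kernel and density normalization; (2) diffusion
pseudotime from a root cell with tip-based branch assignment; (3) per-gene
local (loess-type) regression of expression on pseudotime with an
approximate F-test against a flat profile; (4) Stouffer combination of
per-dataset p-values into meta-p values; (5) consensus gene modules from
Ward clustering of 1 - Pearson r between median fitted profiles; (6)
pseudotime-quintile tumour-vs-control comparisons of module scores.

The branch-assignment step is a deliberately simple tip-path rule (tips
found on geodesics of the kNN graph in diffusion space, cells assigned by
path-additivity residuals) rather than a full branching triangulation; it
is adequate for bifurcating topologies with a single convergence point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import CellMatrix

__all__ = [
    "DiffusionEmbedding",
    "PseudotimeAssignment",
    "diffusion_map",
    "diffusion_pseudotime",
    "pseudotime_de",
    "stouffer_meta",
    "consensus_modules",
    "quintile_module_comparison",
    "loess_smoother_matrix",
]

MODULE_NAMES_4 = ["progenitor", "early-activation", "proto-differentiation", "differentiation"]
PROFILE_GRID = np.linspace(0.0, 1.0, 100)


# ----------------------------------------------------------------------
# preprocessing
# ----------------------------------------------------------------------
def highly_variable_genes(expr: CellMatrix, n_top: int = 800) -> np.ndarray:
    """Indices of the most variable genes by mean-binned normalized dispersion.

    Dispersion (variance / mean of depth-normalized counts) is z-scored
    within 20 equal-occupancy mean-expression bins, so genes with excess
    variance for their expression level rank highest.
    """
    X = np.expm1(expr.lognorm)
    mu = X.mean(axis=1)
    var = X.var(axis=1)
    disp = np.where(mu > 0, var / np.maximum(mu, 1e-12), 0.0)
    edges = np.quantile(mu[mu > 0], np.linspace(0, 1, 21)[1:-1])
    bins = np.digitize(mu, edges)
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        m = bins == b
        sd = disp[m].std()
        z[m] = (disp[m] - disp[m].mean()) / (sd if sd > 0 else 1.0)
    return np.sort(np.argsort(z)[::-1][: min(n_top, expr.n_genes)])


def trajectory_embedding(
    expr: CellMatrix, n_hvg: int = 800, n_pcs: int = 5, seed: int = 0
) -> np.ndarray:
    """PCA embedding of scaled highly variable genes for trajectory inference.

    Trajectory manifolds are low-dimensional, so few components suffice;
    restricting to variable genes and unit-scaling them keeps correlated
    biological programs from being drowned by the flat technical noise of
    the remaining genes.
    """
    hv = highly_variable_genes(expr, n_hvg)
    X = expr.lognorm.T[:, hv]
    sd = X.std(axis=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    from sklearn.decomposition import PCA

    n_pcs = min(n_pcs, X.shape[0] - 1, X.shape[1])
    return PCA(n_components=n_pcs, random_state=seed).fit_transform(X)


# ----------------------------------------------------------------------
# diffusion map
# ----------------------------------------------------------------------
@dataclass
class DiffusionEmbedding:
    """Diffusion components with their eigenvalues and kernel provenance."""

    eigenvalues: np.ndarray  # descending, stationary component excluded
    eigenvectors: np.ndarray  # cells x n_comps, unscaled
    k: int
    kernel: str = "gaussian-adaptive"

    @property
    def components(self) -> np.ndarray:
        """Eigenvectors scaled by their eigenvalues (the DC coordinates)."""
        return self.eigenvectors * self.eigenvalues

    @property
    def dpt_space(self) -> np.ndarray:
        """Eigenvectors scaled by lambda / (1 - lambda), the metric in which
        Euclidean distance approximates diffusion pseudotime distance."""
        lam = self.eigenvalues
        return self.eigenvectors * (lam / (1.0 - lam))


def _density_kernel(X: np.ndarray, k: int = 30) -> np.ndarray:
    """Symmetric density-normalized Gaussian kernel on the kNN graph.

    Per-cell bandwidth is the distance to the ceil(k/2)-th neighbour;
    density normalization divides the kernel by the product of its row
    sums, removing sampling-density bias from the embedding.
    """
    from scipy.spatial.distance import cdist

    n = X.shape[0]
    k = min(k, n - 1)
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    sorted_d = np.sort(D, axis=1)
    sigma = sorted_d[:, int(np.ceil(k / 2)) - 1]
    sigma = np.where(sigma > 0, sigma, np.finfo(float).eps)
    kth = sorted_d[:, k - 1]
    # distance-threshold mask includes ties, so duplicated cells get
    # identical kernel rows regardless of neighbour-list ordering
    mask = D <= kth[:, None]
    mask |= mask.T
    W = np.where(mask, np.exp(-(D**2) / (sigma[:, None] * sigma[None, :])), 0.0)
    np.fill_diagonal(W, 0.0)

    q = W.sum(axis=1)
    if (q == 0).any():
        raise ValueError("disconnected kernel graph; increase k")
    return W / np.outer(q, q)  # density normalization


def transition_matrix(X: np.ndarray, k: int = 30) -> np.ndarray:
    """Row-stochastic diffusion transition matrix (density-normalized kernel
    row-normalized to 1)."""
    W = _density_kernel(X, k=k)
    return W / W.sum(axis=1, keepdims=True)


def diffusion_map(expr: CellMatrix | np.ndarray, k: int = 30, n_comps: int = 10,
                  n_hvg: int = 800, n_pcs: int = 5, seed: int = 0) -> DiffusionEmbedding:
    """Diffusion-map embedding of a cohort (or a raw cells x features array).

    Expression input is first reduced with :func:`trajectory_embedding`
    (highly variable genes, scaling, ``n_pcs`` principal components); the
    symmetric conjugate of the transition matrix is eigendecomposed and
    components 2..n_comps+1 are returned (the stationary eigenvector is
    dropped).
    """
    if isinstance(expr, CellMatrix):
        X = trajectory_embedding(expr, n_hvg=n_hvg, n_pcs=n_pcs, seed=seed)
    else:
        X = np.asarray(expr, dtype=float)
    n = X.shape[0]
    if n < n_comps + 2:
        raise ValueError("need at least n_comps + 2 cells")

    K = _density_kernel(X, k=k)
    # P = D^-1 K with K symmetric: S = D^-1/2 K D^-1/2 shares P's spectrum
    rs = K.sum(axis=1)
    S = K / np.sqrt(np.outer(rs, rs))
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs / np.sqrt(rs)[:, None]  # right eigenvectors of P
    psi = psi / np.linalg.norm(psi, axis=0)

    lam = evals[1 : n_comps + 1]
    comp = psi[:, 1 : n_comps + 1]
    # deterministic sign: largest-magnitude entry positive
    sign = np.sign(comp[np.abs(comp).argmax(axis=0), np.arange(comp.shape[1])])
    comp = comp * np.where(sign == 0, 1.0, sign)
    lam = np.clip(lam, None, 1.0 - 1e-12)
    return DiffusionEmbedding(eigenvalues=lam, eigenvectors=comp, k=k)


# ----------------------------------------------------------------------
# diffusion pseudotime
# ----------------------------------------------------------------------
@dataclass
class PseudotimeAssignment:
    """Min-max-normalized diffusion pseudotime with branch labels."""

    dpt: np.ndarray  # in [0, 1], 0 at root
    branch: np.ndarray  # per-cell branch label
    root: int
    tips: list[int] = field(default_factory=list)


def diffusion_pseudotime(
    emb: DiffusionEmbedding, root: int, n_branches: int = 3,
    branch_names: list[str] | None = None,
    k_graph: int = 15, junction_radius: float = 0.05,
) -> PseudotimeAssignment:
    """Diffusion pseudotime from a root cell with tip-path branch assignment.

    ``dpt(i)`` is the Euclidean distance from the root in the space of
    eigenvectors scaled by lambda/(1-lambda), min-max normalized to [0, 1].

    Branching (``n_branches = 3``, the bifurcating two-progenitor case)
    uses geodesic distances along the ``k_graph``-nearest-neighbour graph
    in the same space: the second progenitor tip maximizes geodesic
    distance from the root; the terminal tip maximizes the summed distance
    to both progenitor tips (on an exact tree geodesic that sum is constant
    along the arms and grows only past the junction, so it cannot select a
    mid-branch cell). Each cell is then assigned to the tip path with the
    smaller path-additivity residual ``d(x, tip) + d(x, terminal) -
    d(tip, terminal)``; cells for which both residuals fall below
    ``junction_radius`` times the inter-tip distance lie past the junction
    and are labelled terminal. With ``n_branches = 1`` all cells share one
    branch; other values assign by geodesic Voronoi of farthest-point tips.
    """
    from scipy.sparse.csgraph import dijkstra
    from sklearn.neighbors import kneighbors_graph

    Y = emb.dpt_space
    n = Y.shape[0]
    if not (0 <= root < n):
        raise ValueError("invalid root cell")
    if n_branches > n:
        raise ValueError("more branches than cells")

    dpt = np.linalg.norm(Y - Y[root], axis=1)
    dpt = dpt / dpt.max() if dpt.max() > 0 else dpt

    if n_branches <= 1:
        name = branch_names[0] if branch_names else "branch_0"
        return PseudotimeAssignment(
            dpt=dpt, branch=np.full(n, name, dtype=object), root=root, tips=[root]
        )

    G = kneighbors_graph(Y, min(k_graph, n - 1), mode="distance")
    G = G.maximum(G.T)

    def _geo(i: int) -> np.ndarray:
        d = dijkstra(G, indices=i)
        return np.where(np.isfinite(d), d, -np.inf)

    d_root = _geo(root)
    if n_branches == 3:
        tip_b = int(np.argmax(d_root))
        d_b = _geo(tip_b)
        tip_t = int(np.argmax(d_root + d_b))
        d_t = _geo(tip_t)
        res_a = d_root + d_t - d_root[tip_t]
        res_b = d_b + d_t - d_b[tip_t]
        eps = junction_radius * d_root[tip_b]
        if branch_names is None:
            branch_names = ["branch_0", "branch_1", "terminal"]
        branch = np.where(
            (res_a < eps) & (res_b < eps),
            branch_names[2],
            np.where(res_a < res_b, branch_names[0], branch_names[1]),
        ).astype(object)
        tips = [root, tip_b, tip_t]
    else:
        tips = [root]
        D = d_root[:, None]
        while len(tips) < n_branches:
            cand = int(D.min(axis=1).argmax())
            tips.append(cand)
            D = np.column_stack([D, _geo(cand)])
        if branch_names is None:
            branch_names = [f"branch_{i}" for i in range(n_branches)]
        branch = np.array([branch_names[a] for a in D.argmin(axis=1)], dtype=object)
    return PseudotimeAssignment(dpt=dpt, branch=branch, root=root, tips=tips)


# ----------------------------------------------------------------------
# loess pseudotime differential expression
# ----------------------------------------------------------------------
def _local_poly_row(x: np.ndarray, x0: float, span_q: int, degree: int) -> np.ndarray:
    """Equivalent-kernel row l(x0): fitted(x0) = l(x0) @ y."""
    d = np.abs(x - x0)
    h = np.sort(d)[span_q - 1]
    h = max(h, np.finfo(float).eps)
    w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3  # tricube
    active = w > 0
    xa = x[active] - x0
    B = np.vander(xa, degree + 1, increasing=True)
    Wb = B * w[active][:, None]
    M = B.T @ Wb
    # e1' (B'WB)^-1 B'W
    try:
        beta_row = np.linalg.solve(M, Wb.T)[0]
    except np.linalg.LinAlgError:
        beta_row = np.linalg.lstsq(M, Wb.T, rcond=None)[0][0]
    row = np.zeros_like(x)
    row[active] = beta_row
    return row


def loess_smoother_matrix(
    x: np.ndarray, span: float = 0.5, degree: int = 2, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Loess hat matrix S (n x n) and grid evaluation matrix L (g x n).

    Local polynomial regression with tricube weights; the neighbourhood of
    each target point is the nearest ``ceil(span * n)`` observations. The
    same matrices serve every gene, so the per-dataset cost is paid once.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    q = max(degree + 2, int(np.ceil(span * n)))
    q = min(q, n)
    S = np.vstack([_local_poly_row(x, x[i], q, degree) for i in range(n)])
    if grid is None:
        grid = PROFILE_GRID
    L = np.vstack([_local_poly_row(x, g, q, degree) for g in grid])
    return S, L


def pseudotime_de(
    expr: CellMatrix,
    pt: PseudotimeAssignment,
    span: float = 0.5,
    cell_mask: np.ndarray | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Loess regression of each gene on pseudotime with an approximate F-test.

    The null model is the intercept-only fit; the test follows the
    analysis-of-variance construction for local regression, with effective
    degrees of freedom from the traces of the smoother-derived quadratic
    forms. Returns per-gene ``p`` plus a 100-point ``fitted_profile`` (as
    columns ``fit_000..fit_099``) on the pseudotime grid. Constant genes
    get p = 1 and a flat profile.
    """
    mask = np.ones(expr.n_cells, dtype=bool) if cell_mask is None else np.asarray(cell_mask)
    x = pt.dpt[mask]
    n = x.size
    if n < 50:
        raise ValueError(f"only {n} cells on the analysed path; need >= 50")
    gene_list = genes if genes is not None else expr.genes
    Y = expr.lognorm[expr.gene_index(gene_list)][:, mask]  # genes x cells

    S, L = loess_smoother_matrix(x, span=span)
    I = np.eye(n)
    R = I - S
    Lam = R.T @ R
    delta1 = np.trace(Lam)
    delta2 = np.trace(Lam @ Lam)
    # null model: projection on the intercept
    H0 = np.full((n, n), 1.0 / n)
    Lam0 = I - H0  # idempotent: both traces are n - 1
    M = Lam0 - Lam
    nu1 = np.trace(M)
    nu2 = np.trace(M @ M)

    fitted = Y @ S.T
    rss1 = ((Y - fitted) ** 2).sum(axis=1)
    ybar = Y.mean(axis=1, keepdims=True)
    rss0 = ((Y - ybar) ** 2).sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / nu1) / (rss1 / delta1)
    df1 = nu1**2 / nu2
    df2 = delta1**2 / delta2
    p = stats.f.sf(F, df1, df2)
    constant = rss0 <= 1e-12
    p = np.where(constant | ~np.isfinite(F), 1.0, p)

    profiles = Y @ L.T  # genes x grid
    profiles[constant] = ybar[constant]
    out = pd.DataFrame({"gene": gene_list, "p": p, "span": span})
    prof_df = pd.DataFrame(
        profiles, columns=[f"fit_{i:03d}" for i in range(L.shape[0])]
    )
    return pd.concat([out, prof_df], axis=1)


# ----------------------------------------------------------------------
# Stouffer meta-analysis
# ----------------------------------------------------------------------
def stouffer_meta(
    p_by_dataset: pd.DataFrame,
    adj_threshold: float = 1e-10,
    nominal_threshold: float = 0.05,
    min_nominal: int = 3,
) -> pd.DataFrame:
    """Combine per-dataset p-values per gene with Stouffer's method.

    ``p_by_dataset`` is genes x datasets (NaN where a gene was not
    testable). ``Z = sum(Phi^-1(1 - p_d)) / sqrt(D)`` over observed
    datasets, ``meta_p = 1 - Phi(Z)``, Bonferroni adjustment over genes.
    A gene is ``significant`` when ``adj_meta_p < adj_threshold`` and it is
    nominally significant (p < ``nominal_threshold``) in at least
    ``min_nominal`` datasets.
    """
    if p_by_dataset.shape[1] < 1:
        raise ValueError("need at least one dataset column")
    P = p_by_dataset.to_numpy(dtype=float)
    if np.nanmin(P) <= 0.0:
        warnings.warn("p = 0 input clamped to the smallest positive float", stacklevel=2)
        P = np.where(P <= 0.0, np.nextafter(0, 1), P)
    if np.nanmax(P) > 1.0:
        raise ValueError("p-values must lie in (0, 1]")

    Zd = stats.norm.isf(P)  # Phi^-1(1 - p)
    D = (~np.isnan(P)).sum(axis=1)
    if (D == 0).any():
        raise ValueError("a gene has no observed p-value in any dataset")
    Z = np.nansum(Zd, axis=1) / np.sqrt(D)
    meta_p = stats.norm.sf(Z)
    adj = np.minimum(1.0, meta_p * P.shape[0])
    n_nominal = np.nansum(P < nominal_threshold, axis=1).astype(int)
    return pd.DataFrame(
        {
            "gene": p_by_dataset.index,
            "meta_p": meta_p,
            "adj_meta_p": adj,
            "n_nominal": n_nominal,
            "n_datasets": D,
            "significant": (adj < adj_threshold) & (n_nominal >= min_nominal),
        }
    ).set_index("gene")


# ----------------------------------------------------------------------
# consensus modules
# ----------------------------------------------------------------------
def consensus_modules(
    fits: list[pd.DataFrame],
    significant_genes: list[str],
    k_modules: int = 4,
) -> pd.DataFrame:
    """Ward clustering of genes by 1 - r between median fitted profiles.

    Each dataset's fitted profile is z-scaled per gene across the
    pseudotime grid (so sequencing depth differences between datasets do
    not dominate), the pointwise median across datasets is taken, pairwise
    Pearson r between gene profiles gives the distance 1 - r, and Ward
    agglomeration is cut at ``k_modules``. With k = 4 the modules are named
    progenitor, early-activation, proto-differentiation and
    differentiation in order of their mean profile's peak position.
    """
    if len(significant_genes) < k_modules:
        raise ValueError("fewer significant genes than requested modules")
    prof_cols = [c for c in fits[0].columns if c.startswith("fit_")]
    stacks = []
    for tab in fits:
        sub = tab.set_index("gene").reindex(significant_genes)[prof_cols].to_numpy()
        mu = np.nanmean(sub, axis=1, keepdims=True)
        sd = np.nanstd(sub, axis=1, keepdims=True)
        stacks.append((sub - mu) / np.where(sd > 1e-12, sd, 1.0))
    median_prof = np.nanmedian(np.stack(stacks), axis=0)  # genes x grid

    sd = median_prof.std(axis=1)
    flat = sd <= 1e-12
    z = (median_prof - median_prof.mean(axis=1, keepdims=True)) / np.where(
        flat, 1.0, sd
    )[:, None]
    r = np.clip((z @ z.T) / z.shape[1], -1.0, 1.0)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    if dist.max() <= 1e-12:
        warnings.warn(
            "all profiles identical: degenerate distance matrix, forcing a split",
            stacklevel=2,
        )
    condensed = squareform((dist + dist.T) / 2.0, checks=False)
    Zlink = linkage(condensed, method="ward")
    raw = fcluster(Zlink, t=k_modules, criterion="maxclust")

    # name modules by the peak position of their mean median-profile
    peaks = {}
    for c in np.unique(raw):
        peaks[c] = PROFILE_GRID[median_prof[raw == c].mean(axis=0).argmax()]
    order = sorted(peaks, key=lambda c: peaks[c])
    if k_modules == 4 and len(order) == 4:
        names = {c: MODULE_NAMES_4[i] for i, c in enumerate(order)}
    else:
        names = {c: f"module_{i + 1}" for i, c in enumerate(order)}
    return pd.DataFrame(
        {
            "gene": significant_genes,
            "module_index": [order.index(c) + 1 for c in raw],
            "module": [names[c] for c in raw],
            "peak_dpt": [peaks[c] for c in raw],
        }
    ).set_index("gene")


# ----------------------------------------------------------------------
# pseudotime-quintile comparisons
# ----------------------------------------------------------------------
def quintile_module_comparison(
    scores: pd.DataFrame | pd.Series,
    pt: PseudotimeAssignment,
    tissue: np.ndarray | pd.Series,
    sample_id: np.ndarray | pd.Series,
    n_bins: int = 5,
    tumour_label: str = "LUAD",
    control_label: str = "control",
) -> dict[str, pd.DataFrame]:
    """Tumour-vs-control comparison of module scores within pseudotime bins.

    Cells are grouped into ``n_bins`` bins by global dpt quantiles, module
    scores are averaged per (sample, bin) and each bin is tested
    tumour vs control with a two-sided rank-sum test on sample means.
    Returns per-module tables of sample means plus a ``p_values`` table
    (modules x bins, NaN where one side is empty).
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_frame()
    tissue = np.asarray(tissue)
    sample_id = np.asarray(sample_id)
    edges = np.quantile(pt.dpt, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    qbin = np.searchsorted(edges, pt.dpt, side="right") - 1
    qbin = np.clip(qbin, 0, n_bins - 1)

    pvals = pd.DataFrame(
        index=scores.columns, columns=[f"q{i + 1}" for i in range(n_bins)], dtype=float
    )
    sample_tables: dict[str, pd.DataFrame] = {}
    for mod in scores.columns:
        sc = scores[mod].to_numpy()
        rows = []
        for q in range(n_bins):
            in_q = qbin == q
            for s in pd.unique(sample_id[in_q]):
                m = in_q & (sample_id == s)
                rows.append(
                    {
                        "quintile": f"q{q + 1}",
                        "sample_id": s,
                        "tissue_type": tissue[m][0],
                        "mean_score": float(sc[m].mean()),
                        "n_cells": int(m.sum()),
                    }
                )
        tab = pd.DataFrame(rows)
        sample_tables[mod] = tab
        for q in range(n_bins):
            sub = tab[tab["quintile"] == f"q{q + 1}"]
            a = sub.loc[sub["tissue_type"] == tumour_label, "mean_score"]
            b = sub.loc[sub["tissue_type"] == control_label, "mean_score"]
            if len(a) == 0 or len(b) == 0:
                warnings.warn(f"empty side in bin q{q + 1} for {mod}", stacklevel=2)
                continue
            pvals.loc[mod, f"q{q + 1}"] = stats.ranksums(a, b)[1]
    return {"p_values": pvals, **sample_tables}
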