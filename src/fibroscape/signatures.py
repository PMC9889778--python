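"""Gene-module scoring, consensus stromal signatures and cell classification.

The module score follows the standard binned-control construction: genes
are binned by mean log-normalized expression, each signature gene draws
expression-matched control genes from its bin, and the per-cell score is
mean(signature) - mean(controls). Stromal demarcation applies a
score-difference rule (fibroblast if fibroblast score - mural score exceeds
a margin and the fibroblast score is positive; symmetric for mural cells;
otherwise unassigned). Cross-cohort subpopulation prediction uses a
centroid-correlation softmax classifier — a deliberately simple,
transparent stand-in for anchor-based label transfer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import softmax

from .containers import CellMatrix, GeneSet

__all__ = [
    "score_gene_module",
    "derive_consensus_signature",
    "classify_stromal",
    "classify_subpopulation",
    "SubpopPrediction",
]

_LFC_PSEUDOCOUNT = 1e-9


def score_gene_module(
    expr: CellMatrix,
    gene_set: GeneSet,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell module score: mean signature expression minus matched controls.

    All genes are ranked into ``n_bins`` bins of equal size by mean
    log-normalized expression; for each signature gene, ``n_ctrl`` control
    genes are sampled from its bin (excluding signature genes, with
    replacement if the bin is smaller than ``n_ctrl``). The score is the
    per-cell mean over signature genes minus the mean over the pooled
    controls. Deterministic given ``seed``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    present = [g for g in gene_set.genes if g in set(expr.genes)]
    if not present:
        raise KeyError(f"no genes of set {gene_set.name!r} present in the matrix")
    X = expr.lognorm
    set_idx = expr.gene_index(present)
    if len(set_idx) == expr.n_genes:
        raise ValueError("gene set covers every gene; no control genes available")

    gene_means = X.mean(axis=1)
    # equal-occupancy bins by rank, as in standard module-score implementations
    ranks = stats.rankdata(gene_means, method="ordinal") - 1
    bins = (ranks * n_bins // expr.n_genes).astype(int)

    rng = np.random.default_rng(seed)
    in_set = np.zeros(expr.n_genes, dtype=bool)
    in_set[set_idx] = True
    ctrl_idx: list[np.ndarray] = []
    for gi in set_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~in_set)
        if pool.size == 0:
            pool = np.flatnonzero(~in_set)
        replace = pool.size < n_ctrl
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl = np.concatenate(ctrl_idx)

    score = X[set_idx].mean(axis=0) - X[ctrl].mean(axis=0)
    return pd.Series(score, index=expr.cell_meta["cell_id"], name=gene_set.name)


def _log2fc(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    """log2 fold change on expm1 of mean log-normalized values."""
    return np.log2(
        (np.expm1(mean_a) + _LFC_PSEUDOCOUNT) / (np.expm1(mean_b) + _LFC_PSEUDOCOUNT)
    )


def derive_consensus_signature(
    expr: CellMatrix,
    labels: pd.Series | np.ndarray,
    whitelist: GeneSet,
    alpha: float = 0.01,
    lfc_min: float = 0.5,
) -> tuple[GeneSet, GeneSet]:
    """Derive fibroblast and mural gene signatures from labelled cells.

    Per gene, a two-group Wilcoxon rank-sum test on log-normalized
    expression with Bonferroni adjustment; genes with adjusted p < ``alpha``
    and \\|log2FC\\| > ``lfc_min`` are assigned to the class they favour and
    intersected with the ``whitelist`` of previously described markers.
    Labels must contain exactly the two classes ``fibroblast`` / ``mural``.
    """
    lab = np.asarray(labels)
    fib_mask = lab == "fibroblast"
    mur_mask = lab == "mural"
    if fib_mask.sum() < 3 or mur_mask.sum() < 3:
        raise ValueError("need >= 3 cells per class to derive signatures")
    X = expr.lognorm
    A, B = X[:, fib_mask], X[:, mur_mask]
    stat, p = stats.ranksums(A, B, axis=1)
    adj_p = np.minimum(1.0, p * expr.n_genes)
    lfc = _log2fc(A.mean(axis=1), B.mean(axis=1))

    wl = set(whitelist.genes)
    fib_genes = [
        g
        for i, g in enumerate(expr.genes)
        if g in wl and adj_p[i] < alpha and lfc[i] > lfc_min
    ]
    mur_genes = [
        g
        for i, g in enumerate(expr.genes)
        if g in wl and adj_p[i] < alpha and lfc[i] < -lfc_min
    ]
    if not fib_genes or not mur_genes:
        warnings.warn("a derived consensus signature is empty", stacklevel=2)
    mk = lambda name, genes: GeneSet(name, genes) if genes else _EmptyGeneSet(name)
    return mk("fibroblast", fib_genes), mk("mural", mur_genes)


class _EmptyGeneSet(GeneSet):
    """Valid-but-empty result of an empty whitelist intersection."""

    def __init__(self, name: str):
        self.name = name
        self.genes = []


def classify_stromal(
    fib: pd.Series | np.ndarray,
    mural: pd.Series | np.ndarray,
    margin: float = 0.1,
    floor: float = 0.0,
) -> pd.Series:
    """Demarcate fibroblasts from mural cells by signature score difference.

    A cell is a fibroblast when ``fib - mural > margin`` and ``fib > floor``;
    mural by the symmetric rule; otherwise unassigned.
    """
    f = np.asarray(fib, dtype=float)
    m = np.asarray(mural, dtype=float)
    if f.shape != m.shape:
        raise ValueError("score vectors have mismatched lengths")
    label = np.full(f.shape, "unassigned", dtype=object)
    label[(f - m > margin) & (f > floor)] = "fibroblast"
    label[(m - f > margin) & (m > floor)] = "mural"
    index = fib.index if isinstance(fib, pd.Series) else None
    return pd.Series(label, index=index, name="stromal_label")


@dataclass
class SubpopPrediction:
    """Per-cell class probabilities and argmax calls."""

    probabilities: pd.DataFrame  # cells x classes
    labels: pd.Series

    def to_csv(self, path) -> None:
        out = self.probabilities.add_prefix("prob_")
        out.insert(0, "label", self.labels)
        out.to_csv(path, index_label="cell_id")


def classify_subpopulation(
    query: CellMatrix,
    reference: CellMatrix,
    label_col: str = "true_type",
    temperature: float = 1.0,
) -> SubpopPrediction:
    """Centroid-correlation softmax classifier across cohorts.

    Class centroids are per-class means of reference log-normalized
    expression on genes shared with the query; each query cell is scored by
    Pearson correlation to every centroid and probabilities are
    ``softmax(correlation / temperature)``.
    """
    shared = [g for g in query.genes if g in set(reference.genes)]
    if len(shared) < 50:
        raise ValueError(f"only {len(shared)} shared genes; need >= 50")
    Xq = query.lognorm[query.gene_index(shared)]
    Xr = reference.lognorm[reference.gene_index(shared)]
    ref_lab = np.asarray(reference.cell_meta[label_col])
    classes = sorted(set(ref_lab))
    for c in classes:
        if (ref_lab == c).sum() < 3:
            raise ValueError(f"reference class {c!r} has fewer than 3 cells")
    centroids = np.column_stack([Xr[:, ref_lab == c].mean(axis=1) for c in classes])

    qc = Xq - Xq.mean(axis=0)
    cc = centroids - centroids.mean(axis=0)
    qn = np.linalg.norm(qc, axis=0)
    cn = np.linalg.norm(cc, axis=0)
    corr = (qc.T @ cc) / np.outer(np.where(qn > 0, qn, 1.0), np.where(cn > 0, cn, 1.0))

    probs = softmax(corr / temperature, axis=1)
    idx = pd.Index(query.cell_meta["cell_id"], name="cell_id")
    prob_df = pd.DataFrame(probs, index=idx, columns=classes)
    labels = pd.Series(
        [classes[i] for i in probs.argmax(axis=1)], index=idx, name="predicted_class"
    )
    return SubpopPrediction(probabilities=prob_df, labels=labels)
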