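"""Digital-cytometry benchmarking: signature matrix, pseudobulk, NNLS.

The reference workflow builds a cell-type signature matrix from annotated
single cells (downsampled per type), simulates pseudobulk mixtures with
known composition — each sample drawing cells from a small number of
patients and then topping fibroblast content up or down to a target
fraction — and estimates per-type abundance scores by non-negative least
squares of each mixture on the signature columns. NNLS is a transparent
stand-in for external digital-cytometry services; externally produced
fraction tables can be loaded as CSV and flow through evaluation and
survival stages unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.optimize import nnls

from .containers import CellMatrix

__all__ = [
    "SignatureMatrix",
    "PseudobulkSet",
    "DeconvResult",
    "build_signature_matrix",
    "simulate_pseudobulk",
    "deconvolve",
    "evaluate_deconvolution",
]

DEFAULT_FIB_TYPES = ("adventitial", "alveolar", "myofibroblast")


@dataclass
class SignatureMatrix:
    """Genes x cell-type mean linear-scale expression over selected genes."""

    values: pd.DataFrame  # index gene, columns cell types
    n_cells_used: dict[str, int]
    provenance: dict = field(default_factory=dict)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


@dataclass
class PseudobulkSet:
    """Simulated mixtures (genes x samples, CPM) with known composition."""

    mixtures: pd.DataFrame
    truth: pd.DataFrame  # samples x cell types, rows sum to 1
    source_patients: dict[str, list[str]]


@dataclass
class DeconvResult:
    """Non-negative per-type scores and within-fibroblast percentages.

    ``fibroblast_pct`` rescales the fibroblast subpopulation scores of each
    sample to sum to 100, the scale on which prognostic cutpoints are
    defined."""

    scores: pd.DataFrame  # samples x cell types, >= 0
    fibroblast_pct: pd.DataFrame
    fib_types: tuple[str, ...]


def _dense_counts(cm: CellMatrix) -> np.ndarray:
    return cm.counts.toarray() if sp.issparse(cm.counts) else np.asarray(cm.counts, float)


def build_signature_matrix(
    ref: CellMatrix,
    label_col: str = "true_type",
    max_cells: int = 500,
    genes_per_type: int = 50,
    alpha: float = 0.01,
    seed: int = 0,
) -> SignatureMatrix:
    """Build a deconvolution signature matrix from an annotated reference.

    Each cell type is randomly downsampled to at most ``max_cells`` cells;
    per type, one-vs-rest rank-sum differential expression on log-normalized
    data selects up to ``genes_per_type`` genes by fold change among those
    with Bonferroni-adjusted p < ``alpha``; the matrix holds per-type mean
    linear-scale (depth-normalized) expression over the union of selections.
    """
    labels = np.asarray(ref.cell_meta[label_col])
    types = sorted(pd.unique(labels))
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    for t in types:
        if (labels == t).sum() < 10:
            raise ValueError(f"cell type {t!r} has fewer than 10 cells")

    rng = np.random.default_rng(seed)
    keep = []
    for t in types:
        idx = np.flatnonzero(labels == t)
        if idx.size > max_cells:
            idx = rng.choice(idx, size=max_cells, replace=False)
        keep.append(np.sort(idx))
    keep = np.concatenate(keep)
    sub = ref.subset_cells(keep)
    sub_labels = np.asarray(sub.cell_meta[label_col])

    X = sub.lognorm
    lin = np.expm1(X)  # linear scale, per-cell depth normalized
    selected: dict[str, list[str]] = {}
    for t in types:
        m = sub_labels == t
        _, p = stats.ranksums(X[:, m], X[:, ~m], axis=1)
        adj = np.minimum(1.0, p * sub.n_genes)
        lfc = np.log2((lin[:, m].mean(axis=1) + 1e-9) / (lin[:, ~m].mean(axis=1) + 1e-9))
        ok = np.flatnonzero((adj < alpha) & (lfc > 0))
        if ok.size == 0:
            raise ValueError(f"cell type {t!r} yields no significant genes")
        top = ok[np.argsort(lfc[ok])[::-1][:genes_per_type]]
        selected[t] = [sub.genes[i] for i in top]

    genes = sorted({g for gl in selected.values() for g in gl})
    gi = sub.gene_index(genes)
    cols = {t: lin[np.ix_(gi, sub_labels == t)].mean(axis=1) for t in types}
    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    return SignatureMatrix(
        values=values,
        n_cells_used={t: int((sub_labels == t).sum()) for t in types},
        provenance={"selected_genes": selected, "max_cells": max_cells, "seed": seed},
    )


def simulate_pseudobulk(
    ref: CellMatrix,
    label_col: str = "true_type",
    fib_types: tuple[str, ...] = DEFAULT_FIB_TYPES,
    n_samples: int = 200,
    cells_per_sample: int = 1000,
    patients_per_sample: int = 3,
    fib_fraction_range: tuple[float, float] = (0.01, 0.50),
    seed: int = 0,
) -> PseudobulkSet:
    """Simulate pseudobulk mixtures with controlled fibroblast content.

    Each sample draws ``cells_per_sample`` cells from
    ``patients_per_sample`` randomly chosen patients, then tops fibroblast
    content up or down to a target fraction drawn uniformly from
    ``fib_fraction_range``. Mixtures are summed counts scaled to counts per
    million; truth fractions are recorded from the realized cell counts.
    """
    labels = np.asarray(ref.cell_meta[label_col])
    patients = np.asarray(ref.cell_meta["patient_id"])
    uniq_pat = pd.unique(patients)
    if len(uniq_pat) < patients_per_sample:
        raise ValueError("not enough patients in the reference")
    is_fib = np.isin(labels, list(fib_types))
    if not is_fib.any() or is_fib.all():
        raise ValueError("reference must contain fibroblast and non-fibroblast types")
    counts = _dense_counts(ref)
    types = sorted(pd.unique(labels))
    rng = np.random.default_rng(seed)

    mix_cols, truth_rows, sources = {}, [], {}
    for s in range(n_samples):
        target = rng.uniform(*fib_fraction_range)
        n_fib = int(round(target * cells_per_sample))
        n_other = cells_per_sample - n_fib
        for attempt in range(100):
            pats = rng.choice(uniq_pat, size=patients_per_sample, replace=False)
            from_pats = np.isin(patients, pats)
            fib_pool = np.flatnonzero(from_pats & is_fib)
            other_pool = np.flatnonzero(from_pats & ~is_fib)
            if fib_pool.size >= n_fib and other_pool.size >= n_other:
                break
        else:
            raise RuntimeError(
                f"sample {s}: could not reach fibroblast fraction {target:.3f} "
                "from available cells after 100 patient draws"
            )
        chosen = np.concatenate(
            [
                rng.choice(fib_pool, size=n_fib, replace=False),
                rng.choice(other_pool, size=n_other, replace=False),
            ]
        )
        agg = counts[:, chosen].sum(axis=1)
        cpm = agg / agg.sum() * 1e6
        name = f"PB{s:03d}"
        mix_cols[name] = cpm
        frac = {t: float((labels[chosen] == t).mean()) for t in types}
        truth_rows.append(pd.Series(frac, name=name))
        sources[name] = list(pats)

    mixtures = pd.DataFrame(mix_cols, index=pd.Index(ref.genes, name="gene"))
    truth = pd.DataFrame(truth_rows)
    return PseudobulkSet(mixtures=mixtures, truth=truth, source_patients=sources)


def deconvolve(
    mixtures: PseudobulkSet | pd.DataFrame,
    sig: SignatureMatrix,
    fib_types: tuple[str, ...] = DEFAULT_FIB_TYPES,
) -> DeconvResult:
    """Estimate per-type abundance scores by non-negative least squares.

    Each mixture column, restricted to the signature genes, is regressed on
    the signature-matrix columns under a non-negativity constraint. The
    within-fibroblast percentage of each subpopulation is
    ``100 * score / sum(scores over fibroblast types)``.
    """
    M = mixtures.mixtures if isinstance(mixtures, PseudobulkSet) else mixtures
    shared = sig.values.index.intersection(M.index)
    if len(shared) < 20:
        raise ValueError(f"only {len(shared)} signature genes shared with the mixture")
    A = sig.values.loc[shared].to_numpy()
    B = M.loc[shared]
    if (B.to_numpy().sum(axis=0) == 0).any():
        raise ValueError("a mixture column is all zero")
    coefs = np.vstack([nnls(A, B[c].to_numpy())[0] for c in B.columns])
    scores = pd.DataFrame(coefs, index=B.columns, columns=sig.cell_types)
    fib = [t for t in fib_types if t in scores.columns]
    denom = scores[fib].sum(axis=1)
    pct = 100.0 * scores[fib].div(denom.where(denom > 0, np.nan), axis=0)
    return DeconvResult(scores=scores, fibroblast_pct=pct, fib_types=tuple(fib))


def evaluate_deconvolution(result: DeconvResult, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-type linear regression of estimated score on true fraction.

    Returns R-squared, slope and n per cell type; R-squared is NA when the
    true fractions are constant.
    """
    common = result.scores.index.intersection(truth.index)
    rows = []
    for t in result.scores.columns:
        if t not in truth.columns:
            continue
        x = truth.loc[common, t].to_numpy()
        y = result.scores.loc[common, t].to_numpy()
        if np.ptp(x) == 0:
            rows.append({"cell_type": t, "r2": np.nan, "slope": np.nan, "n": len(common)})
            continue
        fit = stats.linregress(x, y)
        rows.append(
            {"cell_type": t, "r2": fit.rvalue**2, "slope": fit.slope, "n": len(common)}
        )
    return pd.DataFrame(rows).set_index("cell_type")
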