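"""Core in-memory containers shared by every pipeline stage.

The universal expression carrier is :class:`CellMatrix`: a genes x cells
count matrix (sparse or dense) with a log-normalized layer and per-cell
metadata. It converts losslessly to/from :class:`anndata.AnnData` for
interoperability with the scanpy ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CellMatrix", "GeneSet", "NORM_TARGET"]

#: per-cell total after library-size normalization, before log1p
NORM_TARGET = 10_000.0


def _as_2d(x) -> np.ndarray | sp.spmatrix:
    if sp.issparse(x):
        return x.tocsr()
    arr = np.asarray(x)
    if arr.ndim != 2:
        raise ValueError("expression matrix must be 2-D (genes x cells)")
    return arr


@dataclass
class GeneSet:
    """A named list of unique gene symbols."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @classmethod
    def from_text(cls, path, name: str | None = None) -> "GeneSet":
        """Read one gene symbol per line."""
        with open(path) as fh:
            genes = [ln.strip() for ln in fh if ln.strip()]
        import os

        return cls(name or os.path.splitext(os.path.basename(str(path)))[0], genes)

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.genes) + "\n")


@dataclass
class CellMatrix:
    """Genes x cells counts with a log-normalized layer and cell metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes on rows, cells on columns.
    genes
        Unique gene symbols, one per row.
    cell_meta
        Per-cell metadata (``patient_id``, ``sample_id``, ``tissue_type``,
        ``dataset_id``, plus optional truth columns from the simulators).
    uns
        Unstructured annotations, e.g. planted gene-level truth.
    """

    counts: np.ndarray | sp.spmatrix
    genes: list[str]
    cell_meta: pd.DataFrame
    uns: dict = field(default_factory=dict)
    _lognorm: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = _as_2d(self.counts)
        self.genes = list(self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique")
        if self.counts.shape[0] != len(self.genes):
            raise ValueError("gene list length does not match matrix rows")
        if len(self.cell_meta) != self.counts.shape[1]:
            raise ValueError("cell metadata length does not match matrix columns")
        self.cell_meta = self.cell_meta.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def lognorm(self) -> np.ndarray:
        """log1p of counts scaled to ``NORM_TARGET`` per cell (dense)."""
        if self._lognorm is None:
            c = self.counts.toarray() if sp.issparse(self.counts) else np.asarray(
                self.counts, dtype=float
            )
            totals = c.sum(axis=0)
            totals = np.where(totals > 0, totals, 1.0)
            self._lognorm = np.log1p(c * (NORM_TARGET / totals))
        return self._lognorm

    def gene_index(self, symbols) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [s for s in symbols if s not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        return np.array([lookup[s] for s in symbols], dtype=int)

    def subset_cells(self, mask_or_idx) -> "CellMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        counts = self.counts[:, idx]
        return CellMatrix(
            counts=counts,
            genes=self.genes,
            cell_meta=self.cell_meta.iloc[idx].reset_index(drop=True),
            uns=dict(self.uns),
        )

    # ------------------------------------------------------------------
    def to_anndata(self):
        """Cells x genes :class:`anndata.AnnData` with counts in ``layers``."""
        import anndata as ad

        X = self.counts.T.tocsr() if sp.issparse(self.counts) else self.counts.T.copy()
        adata = ad.AnnData(
            X=X,
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.genes, name="gene")),
        )
        adata.layers["lognorm"] = self.lognorm.T
        adata.uns.update(self.uns)
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "CellMatrix":
        X = adata.X
        counts = X.T.tocsr() if sp.issparse(X) else np.asarray(X).T
        return cls(
            counts=counts,
            genes=list(adata.var_names),
            cell_meta=adata.obs.reset_index(drop=True),
            uns=dict(adata.uns),
        )
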