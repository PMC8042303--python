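"""Single-cell expression profiles per cell type.

Takes a cell-labeled UMI count matrix (AnnData: cells x genes, integer
counts, a ``cell_type`` cell annotation and a boolean ``mito`` gene flag),
applies the standard QC gates (>= 200 expressed genes per cell, mitochondrial
count fraction <= 20%), total-count normalizes to 10,000 with a natural-log
transform, and reduces to gene x cell-type mean profiles with row z-scores.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .specificity import z_transform_rows

MIN_GENES = 200
MAX_MITO_FRAC = 0.20
SCALE = 10_000.0


def _counts(adata: AnnData) -> sparse.csr_matrix:
    X = adata.X
    return X.tocsr() if sparse.issparse(X) else sparse.csr_matrix(np.asarray(X))


def qc_filter(
    adata: AnnData, min_genes: int = MIN_GENES, max_mito_frac: float = MAX_MITO_FRAC
) -> AnnData:
    """Drop cells expressing < min_genes genes or > max_mito_frac mito counts.

    "Expressed" means count > 0. Boundary cells (exactly min_genes genes,
    exactly max_mito_frac mitochondrial fraction) are retained. If no gene
    carries a mitochondrial flag the mito gate is skipped with a warning.
    """
    X = _counts(adata)
    n_genes = (X > 0).sum(axis=1).A1 if hasattr((X > 0).sum(axis=1), "A1") else np.asarray((X > 0).sum(axis=1)).ravel()
    keep = n_genes >= min_genes
    mito = adata.var.get("mito")
    if mito is None or not bool(np.asarray(mito).any()):
        warnings.warn("no mitochondrial genes flagged; skipping mito-fraction filter")
    else:
        mito_mask = np.asarray(mito, dtype=bool)
        total = np.asarray(X.sum(axis=1)).ravel()
        mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito_counts / total, 0.0)
        keep &= frac <= max_mito_frac
    return adata[keep].copy()


def normalize_log(adata: AnnData, scale: float = SCALE) -> AnnData:
    """ln(1 + count / cell_total * scale) per entry (cells stay rows).

    The per-cell vector is invariant to scaling all of that cell's counts.
    """
    X = _counts(adata).astype(float)
    total = np.asarray(X.sum(axis=1)).ravel()
    if np.any(total <= 0):
        raise ValueError("cells with zero total counts must be filtered before normalization")
    X = sparse.diags(scale / total) @ X
    X.data = np.log1p(X.data)
    out = adata.copy()
    out.X = X.tocsr()
    return out


def celltype_means(
    adata: AnnData, label_key: str = "cell_type", cell_types: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene arithmetic mean of (normalized) expression within each label.

    Returns a genes x cell-types DataFrame. When ``cell_types`` is given it
    fixes the column order, every listed type must have >= 1 cell, and any
    cell carrying a label outside the list is an error.
    """
    labels = adata.obs[label_key].astype(str)
    X = adata.X.tocsr() if sparse.issparse(adata.X) else sparse.csr_matrix(np.asarray(adata.X, dtype=float))
    if cell_types is None:
        cell_types = list(pd.unique(labels))
    else:
        unknown = set(labels) - set(cell_types)
        if unknown:
            raise ValueError(f"unknown cell-type labels: {sorted(unknown)}")
    cols = {}
    for t in cell_types:
        idx = np.flatnonzero((labels == t).to_numpy())
        if idx.size == 0:
            raise ValueError(f"cell type with zero cells: {t}")
        cols[t] = np.asarray(X[idx].mean(axis=0)).ravel()
    return pd.DataFrame(cols, index=adata.var_names)


def profile_z(means: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z across cell types (population SD; constant rows -> zeros)."""
    if means.shape[1] < 2:
        raise ValueError("need >= 2 cell-type columns for z-scoring")
    return z_transform_rows(means)
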