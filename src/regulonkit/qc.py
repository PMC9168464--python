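"""Cell quality control, log-normalization, and highly-variable-gene selection.

QC keeps a cell iff it has at least ``min_genes_per_cell`` detected genes
(nonzero entries) AND a mitochondrial count fraction of at most
``max_mito_fraction``; both boundaries are inclusive.  Cells with zero total
counts are dropped and reported separately (their mito fraction is undefined).

Normalization is ln(1 + scale_factor * count / cell_total); HVGs are the top
``n_hvg`` genes by variance of the normalized values, ties broken by gene
order, zero-variance genes never selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CountMatrix, NormalizedMatrix

__all__ = ["QCParams", "filter_cells", "lognormalize", "select_hvg"]


@dataclass(frozen=True)
class QCParams:
    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.20
    mito_prefix: str = "mt-"
    mito_case_insensitive: bool = False
    n_hvg: int = 3000
    scale_factor: float = 10000.0

    def __post_init__(self) -> None:
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if self.n_hvg < 1:
            raise ValueError("n_hvg must be >= 1")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


def filter_cells(
    counts: CountMatrix,
    annot: pd.DataFrame,
    params: QCParams = QCParams(),
) -> tuple[CountMatrix, pd.DataFrame, dict]:
    """Apply the detected-gene and mito-fraction filters.

    Returns the filtered matrix, the matching annotation rows, and a report
    with kept/dropped tallies per criterion (a cell may fail several).
    """
    mat = counts.values
    if params.mito_case_insensitive:
        prefix = params.mito_prefix.lower()
        mito = np.array([g.lower().startswith(prefix) for g in counts.gene_ids])
    else:
        mito = np.array([g.startswith(params.mito_prefix) for g in counts.gene_ids])

    detected = mat.getnnz(axis=1)
    totals = np.asarray(mat.sum(axis=1)).ravel().astype(float)
    mito_counts = np.asarray(mat[:, mito].sum(axis=1)).ravel().astype(float)

    zero_total = totals == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(zero_total, np.nan, mito_counts / np.where(totals, totals, 1))

    fail_genes = detected < params.min_genes_per_cell
    fail_mito = ~zero_total & (mito_frac > params.max_mito_fraction)
    keep = ~zero_total & ~fail_genes & ~fail_mito

    report = {
        "n_input": int(mat.shape[0]),
        "n_kept": int(keep.sum()),
        "n_dropped": int((~keep).sum()),
        "n_fail_min_genes": int(fail_genes.sum()),
        "n_fail_mito": int(fail_mito.sum()),
        "n_zero_total": int(zero_total.sum()),
        "min_genes_per_cell": params.min_genes_per_cell,
        "max_mito_fraction": params.max_mito_fraction,
    }
    kept_idx = np.flatnonzero(keep)
    filtered = CountMatrix(
        mat[kept_idx],
        cell_ids=[counts.cell_ids[i] for i in kept_idx],
        gene_ids=list(counts.gene_ids),
    )
    return filtered, annot.loc[filtered.cell_ids], report


def lognormalize(
    counts: CountMatrix, scale_factor: float = 10000.0
) -> NormalizedMatrix:
    """value(c, g) = ln(1 + scale_factor * count(c, g) / total(c)).

    Requires every cell total > 0 (filter first); zeros map to zeros so the
    result stays sparse.
    """
    totals = np.asarray(counts.values.sum(axis=1)).ravel().astype(float)
    if (totals == 0).any():
        raise ValueError(
            f"{int((totals == 0).sum())} cell(s) have zero total counts; "
            "run filter_cells first"
        )
    mat = counts.values.astype(float).tocsr(copy=True)
    row_of_entry = np.repeat(np.arange(mat.shape[0]), np.diff(mat.indptr))
    mat.data = np.log1p(scale_factor * mat.data / totals[row_of_entry])
    return NormalizedMatrix(
        mat,
        cell_ids=list(counts.cell_ids),
        gene_ids=list(counts.gene_ids),
        scale_factor=scale_factor,
    )


def select_hvg(norm: NormalizedMatrix, n_hvg: int = 3000) -> np.ndarray:
    """Boolean mask of the top ``n_hvg`` genes by variance of normalized values.

    Variance is the unbiased sample variance across cells; ties are broken by
    gene order and zero-variance genes are never flagged.  The mask is also
    stored on ``norm.hvg_mask``.
    """
    n_cells, n_genes = norm.values.shape
    if n_cells < 2:
        raise ValueError("HVG selection requires at least 2 cells")
    mat = norm.values
    mean = np.asarray(mat.mean(axis=0)).ravel()
    mean_sq = np.asarray(mat.multiply(mat).mean(axis=0)).ravel()
    var = (mean_sq - mean**2) * n_cells / (n_cells - 1)
    var = np.maximum(var, 0.0)

    order = np.argsort(-var, kind="stable")  # ties -> gene order
    positive = var[order] > 0
    chosen = order[positive][:n_hvg]
    mask = np.zeros(n_genes, dtype=bool)
    mask[chosen] = True
    norm.hvg_mask = mask
    return mask
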