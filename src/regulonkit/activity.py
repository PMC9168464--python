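"""Per-cell regulon activity by area under the gene-set recovery curve.

For each cell, genes are ranked by decreasing normalized expression (ties —
including the large zero block of sparse data — broken by one fixed random
permutation drawn from ``tie_seed``, so equal-expression genes get an
unbiased, reproducible order).  A regulon's recovery curve counts how many of
its targets appear within the top x ranks; the activity score is the area
under that curve over the top ``top_fraction`` of ranks, normalized by the
maximum achievable area for the same set size, so scores live in [0, 1] and a
perfect recovery scores exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .datatypes import ActivityMatrix, NormalizedMatrix, RegulonSet

__all__ = ["ActivityParams", "rank_genes", "recovery_auc", "score_activity"]


@dataclass(frozen=True)
class ActivityParams:
    top_fraction: float = 0.05
    min_regulon_genes_present: int = 3
    tie_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.min_regulon_genes_present < 1:
            raise ValueError("min_regulon_genes_present must be >= 1")


def rank_genes(values: np.ndarray, tie_seed: int = 0) -> np.ndarray:
    """1-based rank position of every gene in every cell, best rank = 1.

    ``values`` is cells x genes (dense or sparse).  Within a cell genes are
    ordered by decreasing expression; ties are broken by a single random
    permutation drawn from ``tie_seed`` (the same permutation for all cells).
    Returns an integer matrix ``pos`` with ``pos[c, g]`` = rank of gene g in
    cell c.
    """
    if sp.issparse(values):
        values = values.toarray()
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_cells, n_genes = values.shape
    perm = np.random.default_rng(tie_seed).permutation(n_genes)
    # stable sort over permuted columns: ties fall back to the random order
    shuffled = values[:, perm]
    order = perm[np.argsort(-shuffled, axis=1, kind="stable")]
    pos = np.empty((n_cells, n_genes), dtype=np.int64)
    np.put_along_axis(pos, order, np.arange(1, n_genes + 1)[None, :], axis=1)
    return pos


def _max_auc(m: int, T: int) -> int:
    """Area under the best possible recovery curve: m targets at ranks 1..m."""
    if m >= T:
        return T * (T + 1) // 2
    return m * (m + 1) // 2 + m * (T - m)


def recovery_auc(target_ranks, n_genes: int, T: int) -> float:
    """Normalized AUC of the step recovery curve evaluated at x = 1..T.

    ``target_ranks`` are the 1-based, distinct rank positions of the gene
    set's members.  The raw area sums the curve y(x) = #{ranks <= x} over
    x = 1..T; equivalently each rank r contributes max(0, T - r + 1).
    """
    ranks = np.asarray(list(target_ranks), dtype=np.int64)
    m = len(ranks)
    if m == 0:
        raise ValueError("recovery_auc requires at least one target rank")
    if T < 1 or T > n_genes:
        raise ValueError("threshold rank T must be in [1, n_genes]")
    if ranks.min() < 1 or ranks.max() > n_genes or len(np.unique(ranks)) != m:
        raise ValueError("ranks must be distinct integers in [1, n_genes]")
    raw = int(np.clip(T + 1 - ranks, 0, None).sum())
    return raw / _max_auc(m, T)


def score_activity(
    norm: NormalizedMatrix,
    regulons: RegulonSet,
    params: ActivityParams = ActivityParams(),
) -> ActivityMatrix:
    """Score every regulon in every cell; regulons x cells matrix in [0, 1].

    Regulon targets are intersected with the matrix genes; regulons with
    fewer than ``min_regulon_genes_present`` present targets are excluded and
    listed on the result's ``excluded`` attribute.
    """
    n_genes = norm.n_genes
    T = math.ceil(params.top_fraction * n_genes)
    gene_index = {g: i for i, g in enumerate(norm.gene_ids)}

    present: list[tuple[str, np.ndarray]] = []
    excluded: list[str] = []
    for name in regulons.names:
        idx = np.array(
            [gene_index[g] for g in regulons.targets(name) if g in gene_index],
            dtype=np.int64,
        )
        if len(idx) >= params.min_regulon_genes_present:
            present.append((name, idx))
        else:
            excluded.append(name)
    if not present:
        raise ValueError("no scoreable regulons: all target sets are absent "
                         "from the matrix (or below the presence minimum)")

    pos = rank_genes(norm.values, tie_seed=params.tie_seed)
    contrib = np.clip(T + 1 - pos, 0, None)  # per-gene area contribution

    scores = np.empty((len(present), norm.n_cells))
    for r, (_, idx) in enumerate(present):
        scores[r] = contrib[:, idx].sum(axis=1) / _max_auc(len(idx), T)

    return ActivityMatrix(
        scores,
        regulon_names=[name for name, _ in present],
        cell_ids=list(norm.cell_ids),
        top_fraction=params.top_fraction,
        tie_seed=params.tie_seed,
        excluded=excluded,
    )
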