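"""Marker-gene detection and gene-set over-representation.

One-vs-rest Wilcoxon rank-sum per cell type on the log-normalized matrix,
with the Seurat log-fold-change convention (natural log, pseudocount 1,
computed on de-logged means) and a |logFC| pre-filter before testing;
Benjamini-Hochberg adjustment across the genes tested within each type.

Over-representation is an upper-tail hypergeometric test of a query gene
list against user-supplied gene sets within a stated universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import NormalizedMatrix, RegulonSet, validate_annotation

__all__ = ["wilcoxon_markers", "overrepresentation"]


def _logfc(mean_in: np.ndarray, mean_out: np.ndarray) -> np.ndarray:
    """Seurat-style avg_logFC: ln(mean(expm1 x_in)+1) - ln(mean(expm1 x_out)+1),
    the means here already being of expm1-transformed values."""
    return np.log(mean_in + 1.0) - np.log(mean_out + 1.0)


def wilcoxon_markers(
    norm: NormalizedMatrix,
    annot: pd.DataFrame,
    logfc_threshold: float = 0.25,
    method: str = "asymptotic",
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon markers for every cell type.

    Genes with |avg_logFC| below ``logfc_threshold`` are skipped before
    testing.  ``method`` is passed to the rank-sum test: "asymptotic" (normal
    approximation with tie correction; the default, appropriate at realistic
    cell numbers) or "exact".  Returns rows (cell_type, gene, avg_logFC,
    pct_in, pct_out, p_value, p_adjusted) sorted by type then adjusted p.
    """
    annot = validate_annotation(annot, norm.cell_ids)
    type_of = annot["cell_type"].to_numpy()
    types = list(dict.fromkeys(type_of))
    if len(types) < 2:
        raise ValueError("need at least two cell types for one-vs-rest testing")

    dense = norm.values.toarray() if sp.issparse(norm.values) else np.asarray(norm.values)
    expm1 = np.expm1(dense)
    nonzero = dense > 0

    frames = []
    for t in types:
        in_mask = type_of == t
        if in_mask.sum() < 3 or (~in_mask).sum() < 3:
            raise ValueError(f"cell type {t!r} needs >= 3 cells on both sides")
        mean_in = expm1[in_mask].mean(axis=0)
        mean_out = expm1[~in_mask].mean(axis=0)
        logfc = _logfc(mean_in, mean_out)
        tested = np.flatnonzero(np.abs(logfc) >= logfc_threshold)
        if len(tested) == 0:
            continue
        res = stats.mannwhitneyu(
            dense[np.ix_(in_mask, tested)],
            dense[np.ix_(~in_mask, tested)],
            alternative="two-sided",
            method=method,
            use_continuity=False,
            axis=0,
        )
        pvals = np.atleast_1d(res.pvalue)
        padj = multipletests(pvals, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "cell_type": t,
                    "gene": [norm.gene_ids[g] for g in tested],
                    "avg_logFC": logfc[tested],
                    "pct_in": nonzero[in_mask][:, tested].mean(axis=0),
                    "pct_out": nonzero[~in_mask][:, tested].mean(axis=0),
                    "p_value": pvals,
                    "p_adjusted": padj,
                }
            ).sort_values(["p_adjusted", "p_value", "gene"], kind="stable")
        )
    if not frames:
        return pd.DataFrame(
            columns=["cell_type", "gene", "avg_logFC", "pct_in", "pct_out",
                     "p_value", "p_adjusted"]
        )
    return pd.concat(frames, ignore_index=True)


def overrepresentation(
    query_genes,
    gene_sets: RegulonSet | dict[str, tuple[str, ...]],
    universe,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_genes`` in each gene set.

    Sets are intersected with the universe; the query must be a subset of the
    universe.  p is the upper tail P(overlap >= observed); BH across sets.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    query = list(dict.fromkeys(query_genes))
    if not query:
        raise ValueError("empty query gene list")
    stray = [g for g in query if g not in uni]
    if stray:
        raise ValueError(f"{len(stray)} query genes are not in the universe "
                         f"(e.g. {stray[0]!r})")
    if isinstance(gene_sets, RegulonSet):
        sets = {name: gene_sets.targets(name) for name in gene_sets.names}
    else:
        sets = dict(gene_sets)

    qset = set(query)
    rows = []
    for name, members in sets.items():
        inset = [g for g in dict.fromkeys(members) if g in uni]
        overlap = sum(1 for g in inset if g in qset)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(inset),
                                     len(query)))
        rows.append((name, overlap, len(inset), len(universe), len(query), p))
    out = pd.DataFrame(
        rows,
        columns=["gene_set", "overlap", "set_size", "universe_size",
                 "query_size", "p_value"],
    )
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values(["p_value", "gene_set"], kind="stable",
                           ignore_index=True)
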