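"""Connection specificity index (CSI) and regulon module detection.

Two CSI variants over the regulon-regulon Pearson correlation (PCC) matrix:

* ``literal`` (default): CSI(A,B) = n / N where N = K(K-1)/2 is the number of
  unordered off-diagonal regulon pairs and n counts the pairs whose PCC is
  strictly below PCC(A,B).  A global rank transform of the pair correlations.
* ``neighbor``: the classical shared-background form, CSI(A,B) =
  |{C : PCC(A,C) < PCC(A,B) and PCC(B,C) < PCC(A,B)}| / K over all K regulons.

Modules are found by agglomerative clustering of the CSI rows under Euclidean
distance, cutting the tree at ``n_modules`` clusters, and labelling M1..Mk in
decreasing cluster-size order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .datatypes import ActivityMatrix, validate_annotation

__all__ = [
    "CSIParams",
    "drop_zero_variance",
    "pairwise_pcc",
    "compute_csi",
    "detect_modules",
    "module_activity",
    "sankey_table",
    "silhouette_scan",
]


@dataclass(frozen=True)
class CSIParams:
    variant: str = "literal"
    linkage: str = "average"
    n_modules: int = 8
    module_label_prefix: str = "M"

    def __post_init__(self) -> None:
        if self.variant not in ("literal", "neighbor"):
            raise ValueError(f"unknown CSI variant {self.variant!r}")
        if self.linkage not in ("average", "complete", "ward"):
            raise ValueError(f"unsupported linkage {self.linkage!r}")
        if self.n_modules < 2:
            raise ValueError("n_modules must be >= 2")


def drop_zero_variance(activity: ActivityMatrix) -> tuple[ActivityMatrix, list[str]]:
    """Remove constant activity rows (undefined PCC); returns (kept, dropped names)."""
    var = activity.values.var(axis=1)
    keep = var > 0
    dropped = [n for n, k in zip(activity.regulon_names, keep) if not k]
    kept = ActivityMatrix(
        activity.values[keep],
        regulon_names=[n for n, k in zip(activity.regulon_names, keep) if k],
        cell_ids=list(activity.cell_ids),
        top_fraction=activity.top_fraction,
        tie_seed=activity.tie_seed,
        excluded=list(activity.excluded),
    )
    return kept, dropped


def pairwise_pcc(activity: ActivityMatrix) -> pd.DataFrame:
    """Pearson correlation between regulon activity vectors across cells."""
    if activity.values.shape[1] < 2:
        raise ValueError("PCC requires at least 2 cells")
    if (activity.values.var(axis=1) == 0).any():
        raise ValueError(
            "zero-variance activity row; call drop_zero_variance first"
        )
    pcc = np.corrcoef(activity.values)
    np.fill_diagonal(pcc, 1.0)
    return pd.DataFrame(pcc, index=activity.regulon_names,
                        columns=activity.regulon_names)


def compute_csi(pcc: pd.DataFrame, variant: str = "literal") -> pd.DataFrame:
    """CSI matrix from a symmetric PCC matrix; diagonal defined as 1.

    Strict ``<`` throughout, so tied correlations never count toward n; the
    literal variant's values lie on the grid {0, 1/N, ..., (N-1)/N}.
    """
    p = np.asarray(pcc, dtype=float)
    K = p.shape[0]
    if p.shape != (K, K) or not np.allclose(p, p.T, atol=1e-9):
        raise ValueError("PCC matrix must be square and symmetric")
    p = 0.5 * (p + p.T)  # remove ulp-level asymmetry before rank comparisons
    iu = np.triu_indices(K, k=1)
    csi = np.empty_like(p)
    if variant == "literal":
        pair_vals = p[iu]
        N = len(pair_vals)
        sorted_vals = np.sort(pair_vals)
        # pairs strictly below PCC(A,B); (A,B) itself never counts (v < v is false)
        n_below = np.searchsorted(sorted_vals, p, side="left")
        csi = n_below / N
    elif variant == "neighbor":
        for a, b in zip(*iu):
            v = p[a, b]
            csi[a, b] = ((p[a] < v) & (p[b] < v)).sum() / K
        csi = np.triu(csi, k=1)
        csi = csi + csi.T
    else:
        raise ValueError(f"unknown CSI variant {variant!r}")
    np.fill_diagonal(csi, 1.0)
    return pd.DataFrame(csi, index=pcc.index, columns=pcc.columns)


def detect_modules(csi: pd.DataFrame, params: CSIParams = CSIParams()) -> dict[str, str]:
    """Hierarchical clustering of CSI rows into ``n_modules`` modules.

    Euclidean distance between CSI row vectors, agglomerative linkage per
    ``params.linkage``, tree cut with maxclust; labels M1..Mk assigned in
    decreasing cluster-size order (ties by first-regulon input order).
    """
    K = csi.shape[0]
    if params.n_modules > K:
        raise ValueError(f"n_modules={params.n_modules} exceeds {K} regulons")
    dist = ssd.pdist(np.asarray(csi, dtype=float), metric="euclidean")
    with warnings.catch_warnings():
        # ward on a precomputed condensed matrix is valid here: it IS euclidean
        warnings.simplefilter("ignore")
        Z = sch.linkage(dist, method=params.linkage)
    flat = sch.fcluster(Z, t=params.n_modules, criterion="maxclust")

    first_seen = {c: i for i, c in reversed(list(enumerate(flat)))}
    sizes = {c: int((flat == c).sum()) for c in np.unique(flat)}
    ordered = sorted(sizes, key=lambda c: (-sizes[c], first_seen[c]))
    label = {c: f"{params.module_label_prefix}{i + 1}" for i, c in enumerate(ordered)}
    return {name: label[c] for name, c in zip(csi.index, flat)}


def module_activity(
    activity: ActivityMatrix,
    annot: pd.DataFrame,
    assignment: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean activity per (module, cell type) and per (cell, module).

    Entry (M, t) averages activity over the module's regulons and the type's
    cells; the per-cell table (mean over member regulons) supports embedding
    overlays downstream.
    """
    missing = set(activity.regulon_names) - set(assignment)
    if missing:
        raise ValueError(f"{len(missing)} scored regulons lack a module label")
    annot = validate_annotation(annot, activity.cell_ids)
    type_of = annot["cell_type"].to_numpy()
    types = list(dict.fromkeys(type_of))
    modules = sorted(set(assignment[n] for n in activity.regulon_names),
                     key=lambda m: (len(m), m))
    name_idx = {n: i for i, n in enumerate(activity.regulon_names)}

    per_cell = np.empty((len(activity.cell_ids), len(modules)))
    by_type = np.empty((len(modules), len(types)))
    for i, mod in enumerate(modules):
        rows = [name_idx[n] for n in activity.regulon_names if assignment[n] == mod]
        sub = activity.values[rows]
        per_cell[:, i] = sub.mean(axis=0)
        for j, t in enumerate(types):
            by_type[i, j] = sub[:, type_of == t].mean()
    mt = pd.DataFrame(by_type, index=modules, columns=types)
    mt.index.name = "module"
    pc = pd.DataFrame(per_cell, index=activity.cell_ids, columns=modules)
    pc.index.name = "cell_id"
    return mt, pc


def sankey_table(
    rss: pd.DataFrame, assignment: dict[str, str], top_k: int = 20
) -> pd.DataFrame:
    """Per cell type, the top-``top_k`` regulons by RSS with module labels.

    Rows (cell_type, regulon, rank, module), suitable for Sankey rendering.
    """
    if top_k > rss.shape[0]:
        warnings.warn(
            f"top_k={top_k} exceeds the {rss.shape[0]} regulons; listing all",
            stacklevel=2,
        )
        top_k = rss.shape[0]
    rows = []
    for t in rss.columns:
        col = rss[t].reset_index()
        col.columns = ["regulon", "rss"]
        col = col.sort_values(["rss", "regulon"], ascending=[False, True],
                              kind="stable").head(top_k)
        for rank, (_, row) in enumerate(col.iterrows(), start=1):
            rows.append((t, row["regulon"], rank, assignment[row["regulon"]]))
    return pd.DataFrame(rows, columns=["cell_type", "regulon", "rank", "module"])


def silhouette_scan(
    csi: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 15,
    linkage: str = "average",
) -> pd.DataFrame:
    """Mean silhouette width of the module cut for k = k_min..k_max.

    A diagnostic report only — the pipeline never picks k automatically.
    """
    from sklearn.metrics import silhouette_score

    mat = np.asarray(csi, dtype=float)
    dist = ssd.squareform(ssd.pdist(mat, metric="euclidean"))
    rows = []
    k_max = min(k_max, mat.shape[0] - 1)
    for k in range(k_min, k_max + 1):
        params = CSIParams(linkage=linkage, n_modules=k)
        labels = list(detect_modules(csi, params).values())
        if len(set(labels)) < 2:
            continue
        rows.append((k, float(silhouette_score(dist, labels, metric="precomputed"))))
    return pd.DataFrame(rows, columns=["n_modules", "mean_silhouette"])
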