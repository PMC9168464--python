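"""Regulon specificity scores (RSS) and master-regulator ranking.

RSS(R, c) = 1 - sqrt(JSD(p_R, q_c)) where p_R is regulon R's activity row
normalized to a probability distribution over cells, q_c is the uniform
indicator distribution of cell type c's members, and JSD is the
Jensen-Shannon divergence with base-2 entropy (so JSD and RSS both lie in
[0, 1]).  RSS = 1 iff the regulon's normalized activity coincides with the
type's indicator distribution; the top-RSS regulons of a type are its
candidate master regulators.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import ActivityMatrix, validate_annotation

__all__ = ["jsd", "compute_rss", "rank_masters", "positive_fraction"]

_SUM_TOL = 1e-9


def _entropy2(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0*log0 = 0 convention."""
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def jsd(p, q) -> float:
    """Jensen-Shannon divergence between two probability vectors, in [0, 1].

    JSD(p, q) = H((p+q)/2) - (H(p) + H(q)) / 2 with H in bits; inputs must be
    non-negative, equal-length, and sum to 1 within 1e-9.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    for name, v in (("p", p), ("q", q)):
        if (v < 0).any():
            raise ValueError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"{name} sums to {v.sum():.12g}, not 1 (tol 1e-9)")
    m = 0.5 * (p + q)
    val = _entropy2(m) - 0.5 * (_entropy2(p) + _entropy2(q))
    return float(np.clip(val, 0.0, 1.0))


def compute_rss(
    activity: ActivityMatrix, annot: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """RSS for every regulon in every cell type.

    Returns (regulons x cell-types DataFrame, list of regulons excluded
    because their activity row sums to zero — their distribution over cells
    is undefined).
    """
    annot = validate_annotation(annot, activity.cell_ids)
    types = list(dict.fromkeys(annot["cell_type"]))
    type_of = annot["cell_type"].to_numpy()

    row_sums = activity.values.sum(axis=1)
    keep = row_sums > 0
    excluded = [n for n, k in zip(activity.regulon_names, keep) if not k]
    vals = activity.values[keep]
    names = [n for n, k in zip(activity.regulon_names, keep) if k]

    p = vals / vals.sum(axis=1, keepdims=True)
    rss = np.empty((len(names), len(types)))
    for j, t in enumerate(types):
        members = type_of == t
        if not members.any():
            raise ValueError(f"cell type {t!r} has no cells")
        q = members.astype(float) / members.sum()
        for i in range(len(names)):
            rss[i, j] = 1.0 - np.sqrt(jsd(p[i], q))
    out = pd.DataFrame(rss, index=names, columns=types)
    out.index.name = "regulon"
    return out, excluded


def rank_masters(rss: pd.DataFrame, top_k: int = 6) -> pd.DataFrame:
    """Top-``top_k`` regulons per cell type by RSS.

    Ties are broken by regulon name ascending; if ``top_k`` exceeds the number
    of regulons, all are returned with a warning.  Rows: (cell_type, regulon,
    rss, rank), rank starting at 1.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if top_k > rss.shape[0]:
        warnings.warn(
            f"top_k={top_k} exceeds the {rss.shape[0]} available regulons; "
            "returning all",
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
            rows.append((t, row["regulon"], float(row["rss"]), rank))
    return pd.DataFrame(rows, columns=["cell_type", "regulon", "rss", "rank"])


def positive_fraction(
    activity: ActivityMatrix, annot: pd.DataFrame, threshold: float = 0.0
) -> pd.DataFrame:
    """Fraction of each type's cells with activity above ``threshold``
    (regulons x cell types)."""
    annot = validate_annotation(annot, activity.cell_ids)
    type_of = annot["cell_type"].to_numpy()
    types = list(dict.fromkeys(type_of))
    out = np.empty((len(activity.regulon_names), len(types)))
    for j, t in enumerate(types):
        members = type_of == t
        out[:, j] = (activity.values[:, members] > threshold).mean(axis=1)
    df = pd.DataFrame(out, index=activity.regulon_names, columns=types)
    df.index.name = "regulon"
    return df
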