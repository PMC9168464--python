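"""Core in-memory containers shared by every pipeline stage.

Conventions
-----------
* Count and normalized matrices are **cells x genes** everywhere in memory;
  the 10x on-disk dialect (genes as rows) is converted at the I/O boundary.
* Activity matrices are **regulons x cells** (the orientation in which
  specificity scores and correlation matrices are naturally computed).
* Gene identity is the symbol string, case-sensitive, no alias resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "RegulonSet",
    "NormalizedMatrix",
    "ActivityMatrix",
    "validate_annotation",
]


@dataclass
class CountMatrix:
    """Sparse UMI count matrix, cells x genes.

    Parameters
    ----------
    values
        Non-negative integer sparse matrix with one row per cell.
    cell_ids, gene_ids
        Unique ordered identifiers matching the matrix axes.
    """

    values: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.values.eliminate_zeros()
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"matrix has {n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids are not unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class RegulonSet:
    """Named regulons: transcription factor plus ordered target-gene set.

    Regulon names follow the ``TF(+)`` convention, so the TF symbol is
    recoverable from the name.  ``regulons`` maps name -> (tf, targets);
    insertion order is the file order and is preserved everywhere.
    """

    regulons: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for name, (tf, targets) in self.regulons.items():
            if not targets:
                raise ValueError(f"regulon {name!r} has an empty target set")
            if len(set(targets)) != len(targets):
                raise ValueError(f"regulon {name!r} has duplicate targets")
            if not tf:
                raise ValueError(f"regulon {name!r} has an empty TF field")

    @staticmethod
    def tf_from_name(name: str) -> str:
        """``"Srf(+)"`` -> ``"Srf"``; names without parentheses pass through."""
        return name.split("(", 1)[0]

    @property
    def names(self) -> list[str]:
        return list(self.regulons)

    def targets(self, name: str) -> tuple[str, ...]:
        return self.regulons[name][1]

    def __len__(self) -> int:
        return len(self.regulons)

    def __iter__(self):
        return iter(self.regulons)


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, cells x genes.

    ``values[c, g] = ln(1 + scale_factor * count[c, g] / total[c])``; zeros map
    to zeros, so the matrix stays sparse.  ``hvg_mask`` flags the highly
    variable genes once selected (None until then).
    """

    values: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    scale_factor: float
    hvg_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("matrix shape does not match identifier lists")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class ActivityMatrix:
    """Recovery-curve AUC activity scores, regulons x cells, values in [0, 1]."""

    values: np.ndarray
    regulon_names: list[str]
    cell_ids: list[str]
    top_fraction: float
    tie_seed: int
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regulon_names), len(self.cell_ids)):
            raise ValueError("activity shape does not match identifier lists")
        if self.values.size and (
            self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12
        ):
            raise ValueError("activity scores must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.regulon_names, columns=self.cell_ids)
        df.index.name = "regulon"
        return df


def validate_annotation(annot: pd.DataFrame, cell_ids: list[str]) -> pd.DataFrame:
    """Check a cell-annotation table against a matrix's cell ids.

    The table must be indexed by cell id, cover exactly ``cell_ids``, and carry
    a non-empty ``cell_type`` column.  Returns the table reindexed to the
    matrix order.
    """
    if "cell_type" not in annot.columns:
        raise ValueError("annotation lacks a 'cell_type' column")
    if set(annot.index) != set(cell_ids):
        missing = set(cell_ids) - set(annot.index)
        extra = set(annot.index) - set(cell_ids)
        raise ValueError(
            f"annotation does not cover the matrix cells "
            f"({len(missing)} missing, {len(extra)} extra)"
        )
    out = annot.loc[cell_ids]
    if out["cell_type"].isna().any() or (out["cell_type"] == "").any():
        raise ValueError("cell_type must be non-empty for every cell")
    return out
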