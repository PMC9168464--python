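"""Readers and writers for the on-disk formats the pipeline touches.

Supported formats: Matrix Market triplet bundles (matrix.mtx + features.tsv +
barcodes.tsv, both orientations auto-detected), GMT gene-set files, TSV tables
with a header, and JSON run metadata.  Readers never reorder cells or genes
relative to the source files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import CountMatrix, RegulonSet

__all__ = [
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_gmt",
    "write_gmt",
    "read_annotation",
    "write_annotation",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
]

FLOAT_FORMAT = "%.6g"


def _read_id_column(path: Path) -> list[str]:
    """First tab-separated field of each non-blank line, in file order."""
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def _disambiguate(names: list[str]) -> list[str]:
    """Append .1, .2, ... to repeated names in file order."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def read_mtx_triplet(directory: str | Path) -> CountMatrix:
    """Read a 10x-style triplet bundle into a cells x genes CountMatrix.

    The MTX axis whose length matches ``barcodes.tsv`` is taken to be cells;
    if both axes match (square matrix), the 10x convention of genes-as-rows is
    assumed.  Duplicate gene symbols are disambiguated by appending ``.1``,
    ``.2``, ... in file order.
    """
    directory = Path(directory)
    mtx_path = directory / "matrix.mtx"
    for required in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (directory / required).exists():
            raise FileNotFoundError(f"{directory / required} not found")
    mat = scipy.io.mmread(mtx_path)
    if not np.issubdtype(mat.dtype, np.integer):
        data = mat.data if sp.issparse(mat) else np.asarray(mat).ravel()
        if not np.all(data == np.floor(data)):
            raise ValueError(f"{mtx_path}: matrix contains non-integer values")
        mat = mat.astype(np.int64)
    mat = sp.coo_matrix(mat)

    genes = _disambiguate(_read_id_column(directory / "features.tsv"))
    cells = _read_id_column(directory / "barcodes.tsv")
    n_rows, n_cols = mat.shape

    if n_rows == len(genes) and n_cols == len(cells):
        mat = mat.T  # 10x dialect: genes as rows
    elif n_rows == len(cells) and n_cols == len(genes):
        pass
    else:
        raise ValueError(
            f"{mtx_path}: matrix is {n_rows} x {n_cols} but features.tsv has "
            f"{len(genes)} lines and barcodes.tsv has {len(cells)} lines"
        )
    return CountMatrix(sp.csr_matrix(mat), cell_ids=cells, gene_ids=genes)


def write_mtx_triplet(counts: CountMatrix, directory: str | Path) -> None:
    """Write a CountMatrix as a 10x-dialect triplet bundle (genes as rows)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(counts.values.T.astype(np.int64))
    scipy.io.mmwrite(directory / "matrix.mtx", mat, field="integer")
    (directory / "features.tsv").write_text(
        "".join(f"{g}\n" for g in counts.gene_ids), encoding="utf-8"
    )
    (directory / "barcodes.tsv").write_text(
        "".join(f"{c}\n" for c in counts.cell_ids), encoding="utf-8"
    )


def read_gmt(path: str | Path) -> RegulonSet:
    """Parse a GMT file: ``name TAB description TAB gene ...`` per line.

    Blank lines are skipped; duplicate genes within a line are de-duplicated
    keeping the first occurrence; the description field is ignored.
    """
    path = Path(path)
    regulons: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in regulons:
                raise ValueError(f"{path}:{lineno}: duplicate regulon name {name!r}")
            targets = tuple(dict.fromkeys(g for g in fields[2:] if g))
            regulons[name] = (RegulonSet.tf_from_name(name), targets)
    return RegulonSet(regulons)


def write_gmt(regulons: RegulonSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in regulons.names:
            targets = regulons.targets(name)
            fh.write(name + "\tna\t" + "\t".join(targets) + "\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a cell-annotation TSV (cell_id, cell_type, condition, lineage)."""
    annot = pd.read_csv(path, sep="\t", dtype=str).set_index("cell_id")
    return annot


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep="\t", index=True, index_label="cell_id")


def write_table(table: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """TSV with header, UTF-8, floats at 6 significant digits, rows as computed."""
    try:
        table.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
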