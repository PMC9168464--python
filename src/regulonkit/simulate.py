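"""Synthetic scRNA-seq benchmark generator with planted regulatory structure.

Emulates, at reduced scale, a mouse atherosclerosis atlas: ~8 cell types
(SMC, modulated SMC states mSMC1-3, fibroblast, macrophage, endothelial,
T cell), negative-binomial counts with dropout, mitochondrial genes for QC
testing, cell-type-specific regulons, and block-correlated regulon modules.
Every planted fact is returned as ground truth so downstream stages have a
parameter-recovery surface.

Count model: gamma-Poisson (negative binomial) with gene means drawn
log-normally, per-cell depth factors, and a separate per-cell scale for
mitochondrial genes so the mito count fraction varies between cells.  For a
cell of type t, every regulon homed at t has its target genes' means
multiplied by ``activation_fold ** a`` where the activation level ``a`` mixes
a per-cell module latent with per-regulon noise, giving a controllable
within-module correlation between downstream activity vectors.  Dropout is
independent Bernoulli zeroing.  All randomness flows from one seeded
generator, so a fixed seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CountMatrix, RegulonSet
from . import io as rio

__all__ = ["SimulationConfig", "GroundTruth", "simulate_counts", "write_fixture",
           "read_fixture"]

DEFAULT_CELL_TYPES = (
    "SMC", "mSMC1", "mSMC2", "mSMC3",
    "fibroblast", "macrophage", "endothelial", "T cell",
)
DEFAULT_PROPORTIONS = (0.25, 0.12, 0.10, 0.08, 0.15, 0.12, 0.10, 0.08)

SMC_LINEAGE = {"SMC", "mSMC1", "mSMC2", "mSMC3"}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-structure generator.

    ``module_spec`` partitions regulon indices (0-based, cell-type regulons
    first in type order, shared regulons last) into planted modules; None
    means one module per cell type plus one for the shared regulons.
    ``module_correlation`` is the within-module activation-correlation target.
    """

    n_cells: int = 2000
    n_genes: int = 1000
    cell_type_labels: tuple[str, ...] = DEFAULT_CELL_TYPES
    cell_type_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    n_regulons_per_type: int = 3
    n_shared_regulons: int = 2
    targets_per_regulon: int = 20
    activation_fold: float = 4.0
    nb_dispersion: float = 0.4
    dropout_rate: float = 0.3
    mito_gene_fraction: float = 0.013
    module_spec: tuple[tuple[int, ...], ...] | None = None
    module_correlation: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if len(self.cell_type_labels) != len(set(self.cell_type_labels)):
            raise ValueError("cell type labels must be distinct")
        if len(self.cell_type_labels) != len(self.cell_type_proportions):
            raise ValueError("one proportion per cell type is required")
        if abs(sum(self.cell_type_proportions) - 1.0) > 1e-9:
            raise ValueError("cell type proportions must sum to 1 (tol 1e-9)")
        if min(self.cell_type_proportions) < 0:
            raise ValueError("proportions must be non-negative")
        if self.n_regulons_per_type < 0 or self.n_shared_regulons < 0:
            raise ValueError("regulon counts must be non-negative")
        if self.targets_per_regulon < 3:
            raise ValueError("targets_per_regulon must be >= 3")
        if self.activation_fold < 1:
            raise ValueError("activation_fold must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")
        if not 0 <= self.mito_gene_fraction < 1:
            raise ValueError("mito_gene_fraction must be in [0, 1)")
        if not 0 < self.module_correlation <= 1:
            raise ValueError("module_correlation must be in (0, 1]")
        n_mito = int(round(self.mito_gene_fraction * self.n_genes))
        capacity = self.n_genes - n_mito
        demand = self.n_regulons() * self.targets_per_regulon
        if demand > capacity:
            raise ValueError(
                f"{self.n_regulons()} regulons x {self.targets_per_regulon} "
                f"targets = {demand} exceeds the {capacity} non-mitochondrial "
                f"genes available (planted target sets are disjoint)"
            )
        if self.module_spec is not None:
            flat = [i for mod in self.module_spec for i in mod]
            if sorted(flat) != list(range(self.n_regulons())):
                raise ValueError(
                    "module_spec must partition regulon indices "
                    f"0..{self.n_regulons() - 1} exactly once"
                )

    def n_regulons(self) -> int:
        return (self.n_regulons_per_type * len(self.cell_type_labels)
                + self.n_shared_regulons)


@dataclass
class GroundTruth:
    """Planted facts: regulon -> home type (or "shared"), regulon -> module,
    cell -> type."""

    regulon_home_type: dict[str, str]
    module_assignment: dict[str, str]
    cell_type: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.regulon_home_type) != set(self.module_assignment):
            raise ValueError("home-type and module maps cover different regulons")


def _cell_type_counts(config: SimulationConfig) -> list[int]:
    """Deterministic largest-remainder apportionment of cells to types."""
    raw = [p * config.n_cells for p in config.cell_type_proportions]
    counts = [math.floor(x) for x in raw]
    remainder = config.n_cells - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, RegulonSet, GroundTruth]:
    """Generate counts, annotation, regulons, and ground truth.

    Returns (CountMatrix, annotation DataFrame indexed by cell_id with
    cell_type/condition/lineage columns, RegulonSet, GroundTruth).
    """
    rng = np.random.default_rng(config.seed)
    n_cells, n_genes = config.n_cells, config.n_genes
    types = list(config.cell_type_labels)

    # --- gene universe -----------------------------------------------------
    n_mito = int(round(config.mito_gene_fraction * n_genes))
    gene_ids = [f"mt-Gene{i + 1}" for i in range(n_mito)]
    gene_ids += [f"Gene{i + 1:04d}" for i in range(n_genes - n_mito)]
    mito_mask = np.zeros(n_genes, dtype=bool)
    mito_mask[:n_mito] = True

    # --- cells -------------------------------------------------------------
    counts_per_type = _cell_type_counts(config)
    cell_type = np.repeat(np.arange(len(types)), counts_per_type)
    rng.shuffle(cell_type)
    cell_ids = [f"cell{i + 1:05d}" for i in range(n_cells)]

    # --- regulons: disjoint planted target sets ----------------------------
    non_mito_idx = np.flatnonzero(~mito_mask)
    n_reg = config.n_regulons()
    pool = rng.permutation(non_mito_idx)
    regulon_names, home_type = [], []
    target_idx: list[np.ndarray] = []
    k = 0
    for t, tname in enumerate(types):
        for _ in range(config.n_regulons_per_type):
            regulon_names.append(f"Tf{len(regulon_names) + 1:03d}(+)")
            home_type.append(tname)
            target_idx.append(np.sort(pool[k:k + config.targets_per_regulon]))
            k += config.targets_per_regulon
    for _ in range(config.n_shared_regulons):
        regulon_names.append(f"Tf{len(regulon_names) + 1:03d}(+)")
        home_type.append("shared")
        target_idx.append(np.sort(pool[k:k + config.targets_per_regulon]))
        k += config.targets_per_regulon

    # --- module partition ---------------------------------------------------
    if config.module_spec is not None:
        partition = [list(mod) for mod in config.module_spec]
    else:
        by_home: dict[str, list[int]] = {}
        for r, h in enumerate(home_type):
            by_home.setdefault(h, []).append(r)
        partition = [by_home[h] for h in list(types) + ["shared"] if h in by_home]
    module_of = np.empty(n_reg, dtype=int)
    for m, members in enumerate(partition):
        module_of[members] = m

    # --- expression means ---------------------------------------------------
    base_mean = rng.lognormal(mean=-1.0, sigma=1.0, size=n_genes)
    base_mean[mito_mask] *= 6.0  # mitochondrial transcripts are abundant
    depth = rng.lognormal(mean=0.0, sigma=0.5, size=n_cells)
    mito_scale = rng.lognormal(mean=0.0, sigma=0.7, size=n_cells)

    mean = np.outer(depth, base_mean)
    mean[:, mito_mask] *= mito_scale[:, None]

    # --- planted activation with module-shared latents ----------------------
    # activation level a in [0,1]: a = 0.8 + 0.15*(sqrt(rho)*z_module +
    # sqrt(1-rho)*w_regulon), z,w ~ U(-1,1) -> corr(a_r, a_r') = rho within a
    # module among co-activated cells.
    rho = config.module_correlation
    z = rng.uniform(-1.0, 1.0, size=(len(partition), n_cells))
    w = rng.uniform(-1.0, 1.0, size=(n_reg, n_cells))
    level = 0.8 + 0.15 * (np.sqrt(rho) * z[module_of, :] + np.sqrt(1 - rho) * w)
    np.clip(level, 0.0, 1.0, out=level)
    for r in range(n_reg):
        if home_type[r] == "shared":
            active = np.ones(n_cells, dtype=bool)
        else:
            active = cell_type == types.index(home_type[r])
        if active.any():
            mult = config.activation_fold ** level[r, active]
            mean[np.ix_(active, target_idx[r])] *= mult[:, None]

    # --- gamma-Poisson sampling + dropout -----------------------------------
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape, mean * config.nb_dispersion)
    counts = rng.poisson(lam).astype(np.int64)
    if config.dropout_rate > 0:
        counts[rng.random(counts.shape) < config.dropout_rate] = 0

    matrix = CountMatrix(sp.csr_matrix(counts), cell_ids=cell_ids, gene_ids=gene_ids)

    annot = pd.DataFrame(
        {
            "cell_type": [types[t] for t in cell_type],
            "condition": [
                "lesion" if types[t].startswith("mSMC") else "normal"
                for t in cell_type
            ],
            "lineage": [
                "SMC-lineage" if types[t] in SMC_LINEAGE else types[t]
                for t in cell_type
            ],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )

    regulons = RegulonSet(
        {
            name: (RegulonSet.tf_from_name(name),
                   tuple(gene_ids[g] for g in idx))
            for name, idx in zip(regulon_names, target_idx)
        }
    )
    truth = GroundTruth(
        regulon_home_type=dict(zip(regulon_names, home_type)),
        module_assignment={
            regulon_names[r]: f"M{module_of[r] + 1}" for r in range(n_reg)
        },
        cell_type=dict(zip(cell_ids, (types[t] for t in cell_type))),
    )
    return matrix, annot, regulons, truth


def write_fixture(
    bundle: tuple[CountMatrix, pd.DataFrame, RegulonSet, GroundTruth],
    directory: str | Path,
) -> None:
    """Persist a simulated bundle as matrix.mtx + features/barcodes.tsv,
    annotation.tsv, regulons.gmt, ground_truth.json."""
    counts, annot, regulons, truth = bundle
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rio.write_mtx_triplet(counts, directory)
    rio.write_annotation(annot, directory / "annotation.tsv")
    rio.write_gmt(regulons, directory / "regulons.gmt")
    rio.write_json(
        {
            "regulon_home_type": truth.regulon_home_type,
            "module_assignment": truth.module_assignment,
            "cell_type": truth.cell_type,
        },
        directory / "ground_truth.json",
    )


def read_fixture(
    directory: str | Path,
) -> tuple[CountMatrix, pd.DataFrame, RegulonSet, GroundTruth]:
    """Inverse of :func:`write_fixture`."""
    directory = Path(directory)
    counts = rio.read_mtx_triplet(directory)
    annot = rio.read_annotation(directory / "annotation.tsv")
    regulons = rio.read_gmt(directory / "regulons.gmt")
    gt = rio.read_json(directory / "ground_truth.json")
    truth = GroundTruth(
        regulon_home_type=gt["regulon_home_type"],
        module_assignment=gt["module_assignment"],
        cell_type=gt["cell_type"],
    )
    return counts, annot, regulons, truth
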