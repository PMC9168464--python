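import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from regulonkit import (ActivityMatrix, CountMatrix, SimulationConfig,
                        simulate_counts)


@pytest.fixture(scope="session")
def small_config():
    """Compact 4-type fixture configuration used across module tests."""
    return SimulationConfig(
        n_cells=400,
        n_genes=500,
        cell_type_labels=("SMC", "fibroblast", "macrophage", "T cell"),
        cell_type_proportions=(0.3, 0.3, 0.2, 0.2),
        n_regulons_per_type=2,
        n_shared_regulons=1,
        targets_per_regulon=15,
        activation_fold=8.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_counts(small_config)


@pytest.fixture
def tiny_counts():
    """Hand-sized 3-cell x 4-gene count matrix with one mito gene."""
    mat = sp.csr_matrix(
        np.array(
            [
                [5, 0, 2, 1],
                [0, 0, 0, 3],
                [1, 1, 1, 1],
            ]
        )
    )
    return CountMatrix(
        mat,
        cell_ids=["c1", "c2", "c3"],
        gene_ids=["mt-Nd1", "Acta2", "Myh11", "Tagln"],
    )


def make_activity(values, regulon_names=None, cell_ids=None):
    values = np.asarray(values, dtype=float)
    r, c = values.shape
    return ActivityMatrix(
        values,
        regulon_names=regulon_names or [f"R{i}(+)" for i in range(r)],
        cell_ids=cell_ids or [f"cell{j}" for j in range(c)],
        top_fraction=0.05,
        tie_seed=0,
    )


def make_annotation(cell_types, cell_ids=None):
    cell_ids = cell_ids or [f"cell{j}" for j in range(len(cell_types))]
    return pd.DataFrame(
        {"cell_type": list(cell_types), "condition": "normal", "lineage": ""},
        index=pd.Index(cell_ids, name="cell_id"),
    )
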