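import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from homingtrack import (
    ADTMatrix,
    CellDataset,
    CohortSimConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort with a planted effect: 4 paired donors, 3 clusters."""
    cfg = CohortSimConfig(
        seed=42,
        n_donors=4,
        n_clusters=3,
        cells_per_sample_range=(60, 100),
        n_genes=120,
        n_signature_genes_up=15,
        n_signature_genes_down=15,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_cohort():
    """A mid-size effect-bearing cohort used by gating/DGE/scoring tests."""
    cfg = CohortSimConfig(
        seed=7,
        n_donors=8,
        n_clusters=3,
        cells_per_sample_range=(200, 300),
        n_genes=300,
    )
    return cfg, simulate_cohort(cfg)


def make_cells(counts, samples, donors, groups, clusters, genes=None, ids=None):
    """Hand-build a CellDataset from dense counts and metadata lists."""
    counts = np.asarray(counts)
    n, g = counts.shape
    genes = pd.Index(genes if genes is not None else [f"G{i:03d}" for i in range(g)])
    ids = pd.Index(ids if ids is not None else [f"c{i:03d}" for i in range(n)], name="cell")
    obs = pd.DataFrame(
        {"sample": samples, "donor": donors, "group": groups, "cluster": clusters},
        index=ids,
    )
    return CellDataset(sparse.csr_matrix(counts), genes, obs)


def make_adt(counts, cell_ids, markers=("ITGA4", "ITGB1")):
    return ADTMatrix(sparse.csr_matrix(np.asarray(counts)), pd.Index(markers), pd.Index(cell_ids))
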