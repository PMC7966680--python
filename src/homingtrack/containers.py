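"""Core in-memory containers shared across the pipeline.

The central objects are thin, validated wrappers around a sparse count
matrix plus a per-unit metadata table, mirroring the (matrix, obs, var)
layout of the field's standard containers while keeping the dependency
surface small. Conversion to :class:`anndata.AnnData` is provided for
interoperability with the wider single-cell ecosystem.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "CellDataset",
    "ADTMatrix",
    "SpotDataset",
    "NormalizedMatrix",
    "SignatureSet",
    "PseudobulkTable",
]

CELL_OBS_COLUMNS = ("sample", "donor", "group", "cluster")
SPOT_OBS_COLUMNS = ("section", "x", "y", "condition")


def _as_csr_counts(counts) -> sparse.csr_matrix:
    if sparse.issparse(counts):
        mat = counts.tocsr()
    else:
        mat = sparse.csr_matrix(np.asarray(counts))
    if mat.nnz and mat.data.min() < 0:
        raise ValueError("counts must be non-negative")
    return mat


def _check_obs(obs: pd.DataFrame, required: Sequence[str], n_rows: int, kind: str) -> None:
    missing = [c for c in required if c not in obs.columns]
    if missing:
        raise ValueError(f"{kind} metadata is missing required columns: {missing}")
    if len(obs) != n_rows:
        raise ValueError(
            f"{kind} metadata has {len(obs)} rows but the matrix has {n_rows}"
        )
    if obs.index.duplicated().any():
        dups = obs.index[obs.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {kind} ids: {dups}")


@dataclass
class CellDataset:
    """Sparse cell x gene UMI counts with per-cell metadata.

    ``obs`` is indexed by cell id and must carry ``sample``, ``donor``,
    ``group`` and ``cluster`` columns; cluster labels are pipeline inputs
    (clustering itself is upstream of this package).
    """

    counts: sparse.csr_matrix
    genes: pd.Index
    obs: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = _as_csr_counts(self.counts)
        self.genes = pd.Index(self.genes)
        if self.genes.duplicated().any():
            raise ValueError("duplicate gene names")
        if self.counts.shape[1] != len(self.genes):
            raise ValueError(
                f"matrix has {self.counts.shape[1]} genes, names list has {len(self.genes)}"
            )
        _check_obs(self.obs, CELL_OBS_COLUMNS, self.counts.shape[0], "cell")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.obs.index

    def subset_cells(self, mask) -> "CellDataset":
        """Return a new dataset restricted to cells selected by a boolean
        mask or positional index array."""
        mask = np.asarray(mask)
        return CellDataset(self.counts[mask], self.genes, self.obs.iloc[mask] if mask.dtype != bool else self.obs.loc[mask])

    def subset_genes(self, mask) -> "CellDataset":
        mask = np.asarray(mask)
        return CellDataset(self.counts[:, mask], self.genes[mask], self.obs)

    def to_anndata(self):
        """Export as :class:`anndata.AnnData` (optional dependency)."""
        import anndata

        return anndata.AnnData(
            X=self.counts.copy(),
            obs=self.obs.copy(),
            var=pd.DataFrame(index=self.genes),
        )


@dataclass
class ADTMatrix:
    """Cell x surface-marker (antibody-derived tag) counts."""

    counts: sparse.csr_matrix
    markers: pd.Index
    cell_ids: pd.Index

    def __post_init__(self) -> None:
        self.counts = _as_csr_counts(self.counts)
        self.markers = pd.Index(self.markers)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.counts.shape != (len(self.cell_ids), len(self.markers)):
            raise ValueError(
                f"ADT matrix shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.markers)} markers"
            )
        if self.cell_ids.duplicated().any():
            raise ValueError("duplicate cell ids in ADT matrix")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def subset_cells(self, mask) -> "ADTMatrix":
        mask = np.asarray(mask)
        return ADTMatrix(self.counts[mask], self.markers, self.cell_ids[mask])


@dataclass
class SpotDataset:
    """Spot x gene counts from a spatial array, with grid coordinates.

    ``obs`` is indexed by spot id and carries ``section``, ``x``, ``y``
    (integer array indices) and ``condition`` columns. (section, x, y)
    triples must be unique.
    """

    counts: sparse.csr_matrix
    genes: pd.Index
    obs: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = _as_csr_counts(self.counts)
        self.genes = pd.Index(self.genes)
        if self.counts.shape[1] != len(self.genes):
            raise ValueError("gene name list does not match matrix width")
        _check_obs(self.obs, SPOT_OBS_COLUMNS, self.counts.shape[0], "spot")
        coords = self.obs[["section", "x", "y"]]
        if coords.duplicated().any():
            raise ValueError("duplicate (section, x, y) spot coordinates")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def spot_ids(self) -> pd.Index:
        return self.obs.index


@dataclass
class NormalizedMatrix:
    """Normalized expression values with a method tag.

    ``values`` is cells x genes (log-CPM) or cells x markers (CLR); sparse
    for log-CPM (zeros map to zero), dense for CLR.
    """

    values: sparse.spmatrix | np.ndarray
    var_names: pd.Index
    obs_names: pd.Index
    method: str

    def __post_init__(self) -> None:
        self.var_names = pd.Index(self.var_names)
        self.obs_names = pd.Index(self.obs_names)
        if self.values.shape != (len(self.obs_names), len(self.var_names)):
            raise ValueError("normalized matrix shape does not match names")
        data = self.values.data if sparse.issparse(self.values) else self.values
        if not np.all(np.isfinite(data)):
            raise ValueError("normalized values must be finite")

    def column(self, name: str) -> np.ndarray:
        """Dense 1-D vector of one gene/marker across cells."""
        j = self.var_names.get_loc(name)
        col = self.values[:, j]
        return np.asarray(col.todense()).ravel() if sparse.issparse(col) else np.asarray(col).ravel()

    def dense(self) -> np.ndarray:
        return self.values.toarray() if sparse.issparse(self.values) else np.asarray(self.values)


@dataclass
class SignatureSet:
    """A bidirectional gene signature: positive (up) and negative (down)
    marker gene lists, the unit scored by the AUC-ratio statistic."""

    name: str
    positive: list[str] = field(default_factory=list)
    negative: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positive = list(self.positive)
        self.negative = list(self.negative)
        if len(set(self.positive)) != len(self.positive) or len(set(self.negative)) != len(self.negative):
            raise ValueError("duplicate genes within a signature side")
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(f"genes in both signature sides: {sorted(overlap)[:5]}")
        if not self.positive and not self.negative:
            raise ValueError("signature is empty")

    @property
    def genes(self) -> set[str]:
        return set(self.positive) | set(self.negative)

    def to_dict(self) -> dict:
        return {"name": self.name, "positive": self.positive, "negative": self.negative}

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureSet":
        return cls(name=d["name"], positive=d["positive"], negative=d["negative"])


@dataclass
class PseudobulkTable:
    """Gene x sample aggregated UMI counts plus per-sample design covariates.

    ``design`` is indexed by sample and carries the model covariates
    (a blocking factor such as donor, and the group/treatment factor).
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.design.index):
            raise ValueError("pseudobulk columns must match design index (samples)")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("pseudobulk counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("pseudobulk counts must be integers")

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def genes(self) -> pd.Index:
        return self.counts.index
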