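"""Cell- and gene-level quality control and normalization.

The cell filters use strict inequalities for removal ("less than" /
"more than"), so a cell sitting exactly on a bound is kept. RNA is
normalized to log-CPM-style values (``log(1 + scale * count / total)``);
surface-marker (ADT) counts use the centered log-ratio transform with
centering across cells within each marker.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import ADTMatrix, CellDataset, NormalizedMatrix

__all__ = ["QCThresholds", "filter_cells", "filter_genes", "normalize_rna", "clr_adt"]


@dataclass
class QCThresholds:
    """Cell/gene QC bounds; defaults follow standard CITE-seq practice:
    500-15,000 RNA UMI, 300-5,000 detected genes, 100-7,000 ADT UMI,
    at most 20% mitochondrial transcripts, genes detected in >= 10 cells."""

    rna_umi_min: int = 500
    rna_umi_max: int = 15_000
    genes_min: int = 300
    genes_max: int = 5_000
    adt_umi_min: int = 100
    adt_umi_max: int = 7_000
    mito_frac_max: float = 0.20
    gene_min_cells: int = 10
    mito_prefixes: tuple[str, ...] = ("MT-",)

    def __post_init__(self) -> None:
        pairs = [
            ("rna_umi", self.rna_umi_min, self.rna_umi_max),
            ("genes", self.genes_min, self.genes_max),
            ("adt_umi", self.adt_umi_min, self.adt_umi_max),
        ]
        for name, lo, hi in pairs:
            if not lo < hi:
                raise ValueError(f"{name}: min must be < max")
        if not (0.0 <= self.mito_frac_max <= 1.0):
            raise ValueError("mito_frac_max must be in [0, 1]")
        if self.gene_min_cells < 0:
            raise ValueError("gene_min_cells must be >= 0")


def _mito_mask(genes: pd.Index, prefixes) -> np.ndarray:
    mask = np.zeros(len(genes), dtype=bool)
    for p in prefixes:
        mask |= np.asarray(genes.str.startswith(p))
    return mask


def filter_cells(
    cells: CellDataset, adt: ADTMatrix, th: QCThresholds | None = None
) -> tuple[CellDataset, ADTMatrix, pd.DataFrame]:
    """Apply the per-cell QC bounds jointly to RNA and ADT.

    Returns the filtered dataset pair and a report with one row per rule
    counting removals non-exclusively (a cell failing two rules is counted
    under both).
    """
    th = th or QCThresholds()
    missing = cells.cell_ids.difference(adt.cell_ids)
    if len(missing):
        raise ValueError(f"cells missing from ADT matrix: {missing.tolist()[:5]}")
    adt_aligned = adt.subset_cells(adt.cell_ids.get_indexer(cells.cell_ids))

    rna_total = np.asarray(cells.counts.sum(axis=1)).ravel()
    detected = cells.counts.getnnz(axis=1)
    adt_total = np.asarray(adt_aligned.counts.sum(axis=1)).ravel()
    mito = _mito_mask(cells.genes, th.mito_prefixes)
    mito_total = np.asarray(cells.counts[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros_like(rna_total)
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(rna_total > 0, mito_total / np.maximum(rna_total, 1), 1.0)

    fails = {
        "rna_umi_low": rna_total < th.rna_umi_min,
        "rna_umi_high": rna_total > th.rna_umi_max,
        "genes_low": detected < th.genes_min,
        "genes_high": detected > th.genes_max,
        "adt_umi_low": adt_total < th.adt_umi_min,
        "adt_umi_high": adt_total > th.adt_umi_max,
        "mito_frac_high": mito_frac > th.mito_frac_max,
    }
    keep = ~np.logical_or.reduce(list(fails.values()))
    report = pd.DataFrame(
        {"rule": list(fails), "n_removed": [int(m.sum()) for m in fails.values()]}
    )
    report.attrs["n_input"] = cells.n_cells
    report.attrs["n_retained"] = int(keep.sum())
    return cells.subset_cells(keep), adt_aligned.subset_cells(keep), report


def filter_genes(
    cells: CellDataset, th: QCThresholds | None = None, exclude_patterns: tuple[str, ...] = ()
) -> CellDataset:
    """Keep genes detected (count > 0) in at least ``gene_min_cells`` cells;
    drop genes whose names match any of the exclusion regex patterns
    (user-supplied stand-ins for pseudogene/ribosomal annotation lists)."""
    th = th or QCThresholds()
    n_cells_detected = cells.counts.getnnz(axis=0)
    keep = n_cells_detected >= th.gene_min_cells
    for pat in exclude_patterns:
        rx = re.compile(pat)
        keep &= ~cells.genes.map(lambda g: bool(rx.search(g))).to_numpy()
    if not keep.any():
        raise ValueError(
            "no genes retained - review gene_min_cells/exclusion patterns"
        )
    return cells.subset_genes(keep)


def normalize_rna(cells: CellDataset, scale: float = 1e4, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Depth-normalized log expression: ``log(pseudocount + scale*count/total)``.

    With the default pseudocount of 1 zeros map to zero and sparsity is
    preserved. Downstream rank-based scoring depends only on within-cell
    ranks, which this transform preserves from the raw counts.
    """
    totals = np.asarray(cells.counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = cells.cell_ids[totals == 0].tolist()[:5]
        raise ValueError(f"cells with zero total counts (QC should remove them): {bad}")
    mat = cells.counts.tocsr().astype(float)
    inv = scale / totals
    mat = sparse.diags(inv) @ mat
    if pseudocount == 1.0:
        mat.data = np.log1p(mat.data)
        values: sparse.spmatrix | np.ndarray = mat
    else:
        values = np.log(pseudocount + mat.toarray())
    return NormalizedMatrix(values, cells.genes, cells.cell_ids, method="log-CPM")


def clr_adt(adt: ADTMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Centered log-ratio transform of marker counts.

    For each marker, ``log(count + pseudocount)`` centered by its mean
    across cells, so every marker column has exactly zero mean.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    x = adt.counts.toarray().astype(float) + pseudocount
    logx = np.log(x)
    logx -= logx.mean(axis=0, keepdims=True)
    return NormalizedMatrix(logx, adt.markers, adt.cell_ids, method="CLR")
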