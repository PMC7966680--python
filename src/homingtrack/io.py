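"""Readers and writers for the plain-text interchange formats.

Counts travel as MatrixMarket (genes as rows, cells/spots as columns,
1-based indices per the standard; ``.mtx`` or ``.mtx.gz``), gene names
and per-unit metadata as TSV, signatures as JSON
(``{"name", "positive", "negative"}``) or two-column TSV (gene, side).
The dataset kind (cells vs spots) is inferred from the metadata columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import (
    ADTMatrix,
    CellDataset,
    SignatureSet,
    SpotDataset,
    CELL_OBS_COLUMNS,
    SPOT_OBS_COLUMNS,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_adt",
    "write_adt",
    "read_signature",
    "write_signature",
]

MATRIX = "matrix.mtx"
GENES = "genes.tsv"
CELL_META = "cells.tsv"
SPOT_META = "spots.tsv"
ADT_MATRIX = "adt.mtx"
ADT_MARKERS = "adt_markers.tsv"


def _find(directory: Path, name: str) -> Path:
    for cand in (directory / name, directory / f"{name}.gz"):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"{name}[.gz] not found in {directory}")


def _read_mtx(path: Path) -> sparse.csr_matrix:
    return sparse.csr_matrix(spio.mmread(str(path)))


def write_counts(dataset, directory) -> None:
    """Write a CellDataset or SpotDataset as mtx + TSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(directory / MATRIX), dataset.counts.T.astype(int))
    pd.DataFrame({"gene": dataset.genes}).to_csv(directory / GENES, sep="\t", index=False)
    if isinstance(dataset, SpotDataset):
        meta = dataset.obs.reset_index(names="id")[["id", *SPOT_OBS_COLUMNS]]
        meta.to_csv(directory / SPOT_META, sep="\t", index=False)
    else:
        meta = dataset.obs.reset_index(names="id")[["id", *CELL_OBS_COLUMNS]]
        meta.to_csv(directory / CELL_META, sep="\t", index=False)


def read_counts(directory) -> CellDataset | SpotDataset:
    """Read a fixture directory back; the type follows the metadata file.

    Checks matrix/metadata dimension consistency and id uniqueness and
    raises specific errors on mismatch.
    """
    directory = Path(directory)
    mat = _read_mtx(_find(directory, MATRIX)).T.tocsr()
    genes = pd.read_csv(_find(directory, GENES), sep="\t")
    if "gene" not in genes.columns:
        raise ValueError(f"{GENES} must have a 'gene' column")
    genes = pd.Index(genes["gene"])
    if len(genes) != mat.shape[1]:
        raise ValueError(
            f"matrix has {mat.shape[1]} genes but {GENES} lists {len(genes)}"
        )
    try:
        meta_path = _find(directory, SPOT_META)
        columns, kind = SPOT_OBS_COLUMNS, SpotDataset
    except FileNotFoundError:
        meta_path = _find(directory, CELL_META)
        columns, kind = CELL_OBS_COLUMNS, CellDataset
    meta = pd.read_csv(meta_path, sep="\t")
    missing = [c for c in ("id", *columns) if c not in meta.columns]
    if missing:
        raise ValueError(f"{meta_path.name} missing required columns: {missing}")
    if meta["id"].duplicated().any():
        raise ValueError(f"duplicate ids in {meta_path.name}")
    if len(meta) != mat.shape[0]:
        raise ValueError(
            f"matrix has {mat.shape[0]} columns (units) but {meta_path.name} has {len(meta)} rows"
        )
    obs = meta.set_index("id")[list(columns)]
    obs.index.name = "spot" if kind is SpotDataset else "cell"
    return kind(mat, genes, obs)


def write_adt(adt: ADTMatrix, directory) -> None:
    directory = Path(directory)
    spio.mmwrite(str(directory / ADT_MATRIX), adt.counts.T.astype(int))
    pd.DataFrame({"marker": adt.markers}).to_csv(directory / ADT_MARKERS, sep="\t", index=False)


def read_adt(directory, cell_ids) -> ADTMatrix:
    directory = Path(directory)
    mat = _read_mtx(_find(directory, ADT_MATRIX)).T.tocsr()
    markers = pd.read_csv(_find(directory, ADT_MARKERS), sep="\t")["marker"]
    return ADTMatrix(mat, pd.Index(markers), pd.Index(cell_ids))


def write_signature(sig: SignatureSet, path) -> None:
    """JSON (``.json``) or two-column TSV (anything else)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(sig.to_dict(), indent=1))
    else:
        rows = [(g, "positive") for g in sig.positive] + [(g, "negative") for g in sig.negative]
        pd.DataFrame(rows, columns=["gene", "side"]).to_csv(path, sep="\t", index=False)


def read_signature(path, name: str | None = None) -> SignatureSet:
    path = Path(path)
    if path.suffix == ".json":
        d = json.loads(path.read_text())
        for key in ("name", "positive", "negative"):
            if key not in d:
                raise ValueError(f"signature JSON missing {key!r}")
        return SignatureSet.from_dict(d)
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "side"} <= set(df.columns):
        raise ValueError("signature TSV needs 'gene' and 'side' columns")
    bad = set(df["side"]) - {"positive", "negative"}
    if bad:
        raise ValueError(f"unknown signature side labels: {sorted(bad)}")
    return SignatureSet(
        name=name or path.stem,
        positive=df.loc[df["side"] == "positive", "gene"].tolist(),
        negative=df.loc[df["side"] == "negative", "gene"].tolist(),
    )
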