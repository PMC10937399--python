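"""Readers and writers for the plain-text interchange formats.

Dense matrices travel as CSV/TSV with a header row of cell ids and a first
column of gene ids; sparse matrices as Matrix-Market coordinate files with
gene/cell id sidecar TSVs; coordinates as a CSV with columns
``cell_id,x,y[,sample_id]``; cluster labels as a two-column CSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datamodel import ClusterPartition, SpatialDataset

__all__ = [
    "read_dataset",
    "read_coords",
    "write_dataset",
    "write_labels",
    "read_labels",
    "export_augmented",
]


def read_coords(coords_path) -> pd.DataFrame:
    df = pd.read_csv(coords_path)
    cols = list(df.columns)
    if len(cols) >= 4 and cols[3] not in ("sample_id",):
        raise ValueError(
            f"unexpected coordinate column {cols[3]!r}: coordinates must be "
            "2-D (cell_id, x, y[, sample_id]); the azimuthal Gabor filter is "
            "defined azimuthally in the plane"
        )
    expected = ["cell_id", "x", "y"]
    if cols[:3] != expected:
        raise ValueError(f"coordinate columns must start with {expected}, got {cols[:3]}")
    if not np.all(np.isfinite(df[["x", "y"]].to_numpy(dtype=float))):
        raise ValueError("non-finite coordinate values")
    df["cell_id"] = df["cell_id"].astype(str)
    return df


def _read_dense(expr_path, orientation: str):
    df = pd.read_csv(expr_path, sep=None, engine="python", index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression entry in {expr_path}: {exc}") from exc
    if orientation == "cells_by_genes":
        df = df.T
        values = values.T
    gene_ids = [str(g) for g in df.index]
    cell_ids = [str(c) for c in df.columns]
    bad = np.argwhere(values < 0)
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"negative expression value at gene {gene_ids[r]!r}, cell {cell_ids[c]!r}"
        )
    return values, gene_ids, cell_ids


def _read_mtx(expr_path, genes_path, cells_path, orientation: str):
    if genes_path is None or cells_path is None:
        base = Path(expr_path).parent
        genes_path = genes_path or base / "genes.tsv"
        cells_path = cells_path or base / "cells.tsv"
    mat = sp.csr_matrix(scipy.io.mmread(expr_path))
    gene_ids = [l.split("\t")[0] for l in Path(genes_path).read_text().splitlines() if l]
    cell_ids = [l.split("\t")[0] for l in Path(cells_path).read_text().splitlines() if l]
    if orientation == "cells_by_genes":
        mat = mat.T.tocsr()
        gene_ids, cell_ids = cell_ids, gene_ids
    if mat.nnz and mat.data.min() < 0:
        raise ValueError("negative expression value in sparse matrix")
    return mat, gene_ids, cell_ids


def read_dataset(
    expr_path,
    coords_path,
    format: str = "csv_dense",
    genes_path=None,
    cells_path=None,
    orientation: str = "genes_by_cells",
) -> SpatialDataset:
    """Load expression + coordinates into a validated :class:`SpatialDataset`.

    Cells are canonicalized to the expression matrix's column order; the
    coordinate table is reordered to match.  The coordinate file must cover
    every expression column (extra coordinate rows are ignored).
    """
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if format == "csv_dense":
        expr, gene_ids, cell_ids = _read_dense(expr_path, orientation)
    elif format == "mtx_triplet":
        expr, gene_ids, cell_ids = _read_mtx(expr_path, genes_path, cells_path, orientation)
    else:
        raise ValueError(f"unknown format {format!r}")

    cdf = read_coords(coords_path).set_index("cell_id")
    missing = [c for c in cell_ids if c not in cdf.index]
    if missing:
        raise ValueError(f"id mismatch: coordinates missing for cells {missing[:10]}")
    cdf = cdf.loc[cell_ids]
    sample_of = cdf["sample_id"].to_numpy() if "sample_id" in cdf.columns else None
    return SpatialDataset(
        expression=expr,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        coords=cdf[["x", "y"]].to_numpy(dtype=float),
        sample_of=sample_of,
    )


def write_dataset(ds: SpatialDataset, expr_path, coords_path) -> None:
    """Write a dataset as dense CSV + coordinates CSV (round-trips losslessly
    for integer counts, within float repr precision otherwise)."""
    df = pd.DataFrame(ds.expression_dense(), index=ds.gene_ids, columns=ds.cell_ids)
    df.index.name = "gene_id"
    df.to_csv(expr_path)
    cdf = pd.DataFrame({"cell_id": ds.cell_ids, "x": ds.coords[:, 0], "y": ds.coords[:, 1]})
    if ds.sample_of is not None:
        cdf["sample_id"] = ds.sample_of
    cdf.to_csv(coords_path, index=False)


def write_labels(partition: ClusterPartition, cell_ids, path) -> None:
    """Write a two-column (cell_id, cluster) CSV."""
    cell_ids = list(cell_ids)
    if partition.labels.size != len(cell_ids):
        raise ValueError("partition does not cover the given cell ids")
    pd.DataFrame({"cell_id": cell_ids, "cluster": partition.labels}).to_csv(path, index=False)


def read_labels(path, cell_ids=None) -> ClusterPartition:
    df = pd.read_csv(path, dtype={"cell_id": str})
    if cell_ids is not None:
        df = df.set_index("cell_id")
        missing = [c for c in cell_ids if str(c) not in df.index]
        if missing:
            raise ValueError(f"id mismatch: labels missing for cells {missing[:10]}")
        df = df.loc[[str(c) for c in cell_ids]].reset_index()
    return ClusterPartition(df["cluster"].to_numpy(dtype=int), list(df["cell_id"]))


def export_augmented(aug, gene_ids, path_mtx, path_rows) -> None:
    """Export an augmented matrix as Matrix-Market plus a row-annotation TSV
    tagging each row with its (gene, block) origin."""
    scipy.io.mmwrite(str(path_mtx), sp.coo_matrix(aug.values))
    with open(path_rows, "w") as fh:
        fh.write("gene\tblock\n")
        for block in ("own", "mean", "agf"):
            for g in gene_ids:
                fh.write(f"{g}\t{block}\n")
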