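"""Core data containers.

The central object is :class:`SpatialDataset`, a gene x cell expression
matrix paired with 2-D cell coordinates.  Expression is stored genes-as-rows
(``p x N``), matching the orientation in which the spatial kernels and the
neighbor-augmented matrix are defined.  All per-cell arrays (coordinates,
sample labels, cluster labels) share the expression matrix's column order,
which is canonicalized at load time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["SpatialDataset", "ClusterPartition", "RunConfig"]


def _is_sparse(x) -> bool:
    return sp.issparse(x)


@dataclass
class SpatialDataset:
    """Gene x cell expression matrix with per-cell 2-D coordinates.

    Parameters
    ----------
    expression
        ``p x N`` matrix of nonnegative reals (dense ndarray or scipy
        sparse).  Rows are genes, columns are cells.
    gene_ids, cell_ids
        Unique identifiers for the ``p`` rows and ``N`` columns.
    coords
        ``N x 2`` array of (x, y) positions in arbitrary but consistent
        length units (the Gaussian envelope is scale-invariant, so the
        unit never enters downstream results).
    sample_of
        Optional length-``N`` array of sample identifiers; when present,
        spatial neighborhoods are constrained within samples.
    """

    expression: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    coords: np.ndarray
    sample_of: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not _is_sparse(self.expression):
            self.expression = np.asarray(self.expression, dtype=float)
            if self.expression.ndim != 2:
                raise ValueError("expression must be a 2-D matrix")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.coords = np.asarray(self.coords, dtype=float)
        p, n = self.expression.shape
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} expression rows")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} expression columns")
        if len(set(self.gene_ids)) != p:
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                "coords must be N x 2: the azimuthal Gabor filter is defined "
                "in 2-D; a third coordinate column is not supported"
            )
        if self.coords.shape[0] != n:
            raise ValueError(f"{self.coords.shape[0]} coordinate rows for {n} cells")
        if self.sample_of is not None:
            self.sample_of = np.asarray(self.sample_of)
            if self.sample_of.shape[0] != n:
                raise ValueError("sample_of length mismatch")
        dense = self.expression.toarray() if _is_sparse(self.expression) else self.expression
        if not np.all(np.isfinite(dense)):
            raise ValueError("expression contains non-finite entries")
        if dense.min(initial=0.0) < 0:
            raise ValueError("expression contains negative entries")

    # -- basic shape accessors -------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_cells(self) -> int:
        return self.expression.shape[1]

    def expression_dense(self) -> np.ndarray:
        if _is_sparse(self.expression):
            return np.asarray(self.expression.todense(), dtype=float)
        return self.expression

    def cell_totals(self) -> np.ndarray:
        """Per-cell total counts (column sums)."""
        if _is_sparse(self.expression):
            return np.asarray(self.expression.sum(axis=0)).ravel()
        return self.expression.sum(axis=0)

    # -- subsetting -------------------------------------------------------
    def subset_cells(self, index: np.ndarray) -> "SpatialDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        expr = self.expression[:, index]
        return SpatialDataset(
            expression=expr,
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in index],
            coords=self.coords[index],
            sample_of=None if self.sample_of is None else self.sample_of[index],
        )

    def subset_genes(self, index: np.ndarray) -> "SpatialDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpatialDataset(
            expression=self.expression[index, :],
            gene_ids=[self.gene_ids[i] for i in index],
            cell_ids=list(self.cell_ids),
            coords=self.coords.copy(),
            sample_of=None if self.sample_of is None else self.sample_of.copy(),
        )

    def with_expression(self, expression) -> "SpatialDataset":
        return SpatialDataset(
            expression=expression,
            gene_ids=list(self.gene_ids),
            cell_ids=list(self.cell_ids),
            coords=self.coords.copy(),
            sample_of=None if self.sample_of is None else self.sample_of.copy(),
        )

    def split_by_sample(self) -> list[tuple[str, np.ndarray]]:
        """Return (sample_id, cell index array) pairs, in first-seen order."""
        if self.sample_of is None:
            return [("sample0", np.arange(self.n_cells))]
        seen: dict = {}
        for i, s in enumerate(self.sample_of):
            seen.setdefault(s, []).append(i)
        return [(str(s), np.asarray(ix)) for s, ix in seen.items()]


@dataclass
class ClusterPartition:
    """A hard partition of cells into integer-labeled clusters."""

    labels: np.ndarray
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one label per cell")
        if self.labels.size == 0:
            raise ValueError("empty partition")
        if self.cell_ids is not None and len(self.cell_ids) != self.labels.size:
            raise ValueError("cell_ids / labels length mismatch")

    @property
    def n_cells(self) -> int:
        return self.labels.size

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def relabel_by_size(self) -> "ClusterPartition":
        """Canonicalize labels to 0..K-1 in order of decreasing cluster size.

        Ties in size are broken by the smallest original label, so the
        canonical form is deterministic.
        """
        uniq, counts = np.unique(self.labels, return_counts=True)
        order = np.lexsort((uniq, -counts))
        mapping = {int(uniq[j]): rank for rank, j in enumerate(order)}
        new = np.array([mapping[int(l)] for l in self.labels], dtype=int)
        return ClusterPartition(new, self.cell_ids)

    def as_mapping(self) -> dict:
        ids = self.cell_ids or [str(i) for i in range(self.n_cells)]
        return {c: int(l) for c, l in zip(ids, self.labels)}


_MODE_LAMBDA = {"cell_typing": 0.2, "domain_segmentation": 0.8}


@dataclass
class RunConfig:
    """Parameters of one embedding-and-clustering run.

    ``lambda_mix`` trades off a cell's own transcriptome (0) against its
    neighborhood features (1); the conventional operating points are 0.2
    for cell typing and 0.8 for tissue-domain segmentation, applied
    automatically when ``mode`` is set and ``lambda_mix`` is left None.
    """

    lambda_mix: float | None = None
    k_geom: int = 15
    k_expr: int = 50
    n_pcs: int = 20
    resolution: float = 1.0
    seed: int = 0
    mode: str = "custom"
    mu: float = 1.5
    agf_reference_ordinal: int | None = None  # override for the AGF envelope

    def __post_init__(self) -> None:
        if self.mode not in ("cell_typing", "domain_segmentation", "custom"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.lambda_mix is None:
            if self.mode == "custom":
                raise ValueError("mode='custom' requires an explicit lambda_mix")
            self.lambda_mix = _MODE_LAMBDA[self.mode]
        self.lambda_mix = float(self.lambda_mix)
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise ValueError("lambda_mix must lie in [0, 1]")
        for name in ("k_geom", "k_expr", "n_pcs"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a flat ``key=value`` text file."""
        kwargs: dict = {}
        casts = {
            "lambda_mix": float, "k_geom": int, "k_expr": int, "n_pcs": int,
            "resolution": float, "seed": int, "mode": str, "mu": float,
            "agf_reference_ordinal": int,
        }
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in casts:
                    raise ValueError(f"unknown config key {key!r}")
                kwargs[key] = casts[key](value.strip())
        return cls(**kwargs)
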