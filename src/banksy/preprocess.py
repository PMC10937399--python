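"""Dataset-level filtering and normalization applied before embedding.

The canonical pipeline order is: cell filter -> gene filter -> total-count
normalization -> log1p -> highly-variable-gene selection.  Each step is a
pure function returning a new dataset (plus a :class:`FilterReport` for the
filters), so recipes can be reordered per dataset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .datamodel import SpatialDataset

__all__ = [
    "FilterReport",
    "filter_cells_by_total",
    "filter_genes_by_prevalence",
    "normalize_total",
    "log1p_transform",
    "select_hvg",
    "crop_radius",
]


@dataclass
class FilterReport:
    """What a filter removed and why."""

    cells_removed: int = 0
    genes_removed: int = 0
    reasons: list[str] = field(default_factory=list)
    thresholds_used: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cells_removed": self.cells_removed,
            "genes_removed": self.genes_removed,
            "reasons": self.reasons,
            "thresholds_used": self.thresholds_used,
        }


def _resolve_threshold(spec, totals: np.ndarray) -> float:
    """A threshold is either an absolute count or ("percentile", q).

    Percentiles use linear interpolation (numpy's default definition).
    """
    if isinstance(spec, tuple) and len(spec) == 2 and spec[0] == "percentile":
        return float(np.percentile(totals, spec[1]))
    return float(spec)


def filter_cells_by_total(ds: SpatialDataset, low=0.0, high=np.inf):
    """Keep cells whose total count t satisfies low <= t <= high.

    ``low``/``high`` are absolute counts or ``("percentile", q)`` tuples;
    in percentile mode cells strictly below the low percentile or strictly
    above the high percentile are removed.
    """
    totals = ds.cell_totals()
    lo = _resolve_threshold(low, totals)
    hi = _resolve_threshold(high, totals)
    if lo > hi:
        raise ValueError(f"low threshold {lo} exceeds high threshold {hi}")
    keep = (totals >= lo) & (totals <= hi)
    if not keep.any():
        raise ValueError("empty dataset after filtering: no cell total within bounds")
    report = FilterReport(
        cells_removed=int((~keep).sum()),
        reasons=[f"total count outside [{lo}, {hi}]"],
        thresholds_used={"low": lo, "high": hi},
    )
    return ds.subset_cells(keep), report


def filter_genes_by_prevalence(ds: SpatialDataset, min_cells):
    """Keep genes with a nonzero count in at least ``min_cells`` cells.

    A fractional ``min_cells`` in (0, 1) is interpreted against the number
    of cells with a ceiling, so 0.01 means "at least 1% of cells".
    """
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    threshold = (
        math.ceil(min_cells * ds.n_cells) if 0 < min_cells < 1 else int(min_cells)
    )
    expr = ds.expression
    if sp.issparse(expr):
        prevalence = np.asarray((expr > 0).sum(axis=1)).ravel()
    else:
        prevalence = (expr > 0).sum(axis=1)
    keep = prevalence >= threshold
    if not keep.any():
        raise ValueError("empty dataset after filtering: no gene passes prevalence")
    report = FilterReport(
        genes_removed=int((~keep).sum()),
        reasons=[f"nonzero in fewer than {threshold} cells"],
        thresholds_used={"min_cells": threshold},
    )
    return ds.subset_genes(keep), report


def normalize_total(ds: SpatialDataset, target="median") -> SpatialDataset:
    """Scale each cell's column to a common total count.

    ``target`` is either ``"median"`` (the median of the pre-normalization
    per-cell totals) or a fixed positive number.
    """
    totals = ds.cell_totals()
    if np.any(totals == 0):
        raise ValueError(
            "zero-total cell encountered; filter cells by total count first"
        )
    value = float(np.median(totals)) if target == "median" else float(target)
    if value <= 0:
        raise ValueError("normalization target must be positive")
    scale = value / totals
    expr = ds.expression
    if sp.issparse(expr):
        out = expr @ sp.diags(scale)
    else:
        out = expr * scale[np.newaxis, :]
    return ds.with_expression(out)


def log1p_transform(ds: SpatialDataset) -> SpatialDataset:
    """Replace every entry x with ln(1 + x)."""
    expr = ds.expression
    if sp.issparse(expr):
        out = expr.copy()
        out.data = np.log1p(out.data)
    else:
        out = np.log1p(expr)
    return ds.with_expression(out)


def select_hvg(ds: SpatialDataset, n_top: int) -> SpatialDataset:
    """Keep the ``n_top`` genes with the largest expression variance.

    The dispersion statistic is the per-gene variance of the (typically
    log-normalized) expression values; genes are ranked descending with
    ties broken by original gene order, and the retained genes keep their
    original order.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > ds.n_genes:
        raise ValueError(f"n_top={n_top} exceeds {ds.n_genes} genes")
    expr = ds.expression_dense()
    variances = expr.var(axis=1)
    order = np.lexsort((np.arange(ds.n_genes), -variances))
    keep = np.sort(order[:n_top])
    return ds.subset_genes(keep)


def crop_radius(ds: SpatialDataset, radius: float, center=None):
    """Generic utility: keep cells within ``radius`` of ``center`` (default:
    the coordinate centroid)."""
    center = ds.coords.mean(axis=0) if center is None else np.asarray(center, float)
    keep = np.linalg.norm(ds.coords - center, axis=1) <= radius
    if not keep.any():
        raise ValueError("empty dataset after cropping")
    report = FilterReport(
        cells_removed=int((~keep).sum()),
        reasons=[f"outside radius {radius} of {center.tolist()}"],
        thresholds_used={"radius": radius},
    )
    return ds.subset_cells(keep), report
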