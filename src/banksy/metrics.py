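"""Evaluation and comparison computations.

NCC (normalized cross-connectivity) quantifies spatial intermingling of
clusters through the directed spatial-neighbor relation; the cluster
consensus matches labels across clustering solutions by maximum-overlap
linear sum assignment (Hungarian algorithm); metagene scores contrast two
DEG sets per cell; label smoothing majority-filters a reference annotation
on the spatial graph; ARI is the standard chance-corrected pair-counting
agreement.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .datamodel import ClusterPartition
from .features import zscale_rows
from .spatial_graph import SpatialNeighborGraph

__all__ = [
    "ncc",
    "contingency",
    "consensus_match",
    "metagene_score",
    "smooth_labels",
    "ari",
]


def _label_array(p) -> np.ndarray:
    return p.labels if isinstance(p, ClusterPartition) else np.asarray(p, dtype=int)


def ncc(partition: ClusterPartition, graph: SpatialNeighborGraph) -> tuple[np.ndarray, list[int]]:
    """Normalized cross-connectivity matrix of a clustering solution.

    Entry (r, q) — reference cluster r on rows, query cluster q on columns —
    is the number of directed spatial-neighbor edges from cells of r into
    cells of q, divided by the number of edges from r into itself:

        NCC[r, q] = sum_{u in s_r} sum_{v in eta(u)} 1[v in s_q]
                    / sum_{u in s_r} sum_{v in eta(u)} 1[v in s_r]

    The diagonal is 1 whenever the denominator is positive; a reference
    cluster whose neighborhoods contain none of its own members yields a
    NaN row with a warning.  Returns (matrix, sorted cluster labels).
    """
    labels = _label_array(partition)
    if labels.size != graph.n_cells:
        raise ValueError("partition / graph cell-count mismatch")
    uniq, compact = np.unique(labels, return_inverse=True)
    k = uniq.size
    counts = np.zeros((k, k), dtype=float)  # counts[r, q]: edges r -> q
    src = np.repeat(compact, graph.k)
    dst = compact[graph.neighbors.ravel()]
    np.add.at(counts, (src, dst), 1)
    denom = np.diag(counts).copy()
    out = np.full((k, k), np.nan)
    bad = denom == 0
    if bad.any():
        warnings.warn(
            f"reference cluster(s) {uniq[bad].tolist()} have no within-cluster "
            "spatial edges; NCC undefined (NaN) for those rows"
        )
    ok = ~bad
    out[ok] = counts[ok] / denom[ok, None]
    return out, [int(l) for l in uniq]


def contingency(a, b) -> tuple[np.ndarray, list[int], list[int]]:
    """Cluster-overlap contingency matrix: entry (i, j) counts cells shared
    by cluster i of ``a`` and cluster j of ``b``."""
    la, lb = _label_array(a), _label_array(b)
    if la.size != lb.size:
        raise ValueError("partitions cover different cell sets")
    ua, ca = np.unique(la, return_inverse=True)
    ub, cb = np.unique(lb, return_inverse=True)
    M = np.zeros((ua.size, ub.size), dtype=int)
    np.add.at(M, (ca, cb), 1)
    return M, [int(l) for l in ua], [int(l) for l in ub]


def consensus_match(a: ClusterPartition, b: ClusterPartition):
    """Optimal one-to-one cluster matching between two partitions.

    Solves the maximum-overlap linear sum assignment on the contingency
    matrix (Hungarian algorithm) and relabels ``b`` into ``a``'s label
    space; clusters of ``b`` left unmatched keep fresh labels above
    ``a``'s range.

    Returns ``(mapping, total_overlap, relabeled_b)`` where ``mapping``
    maps b-labels to a-labels for the matched pairs.
    """
    M, labels_a, labels_b = contingency(a, b)
    rows, cols = linear_sum_assignment(M, maximize=True)
    mapping = {labels_b[j]: labels_a[i] for i, j in zip(rows, cols)}
    total = int(M[rows, cols].sum())
    next_label = max(labels_a) + 1
    full = dict(mapping)
    for l in labels_b:
        if l not in full:
            full[l] = next_label
            next_label += 1
    lb = _label_array(b)
    relabeled = ClusterPartition(
        np.array([full[int(l)] for l in lb], dtype=int),
        b.cell_ids if isinstance(b, ClusterPartition) else None,
    )
    return mapping, total, relabeled


def metagene_score(
    expr: np.ndarray,
    gene_ids: list[str],
    up_in_1: list[str],
    up_in_2: list[str],
    zscale: bool = True,
) -> np.ndarray:
    """Per-cell metagene contrast of subcluster 2 versus subcluster 1.

    ``expr`` is the p x N expression over the union of the two subclusters
    only; it is z-scaled per gene over those cells (set ``zscale=False`` if
    already scaled).  The score is mean(z of up-in-2 genes) minus
    mean(z of up-in-1 genes) for each cell.  Passing the matching rows of
    the neighborhood-mean matrix gives the companion neighbor-expression
    metagene.
    """
    if not up_in_1 or not up_in_2:
        raise ValueError("both gene sets must be nonempty")
    if set(up_in_1) & set(up_in_2):
        raise ValueError("gene sets must be disjoint")
    index = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in (*up_in_1, *up_in_2) if g not in index]
    if missing:
        raise ValueError(f"genes not in matrix: {missing}")
    Z = zscale_rows(expr) if zscale else np.asarray(expr, dtype=float)
    i1 = [index[g] for g in up_in_1]
    i2 = [index[g] for g in up_in_2]
    return Z[i2].mean(axis=0) - Z[i1].mean(axis=0)


def smooth_labels(
    labels: ClusterPartition | np.ndarray,
    graph: SpatialNeighborGraph,
    rounds: int = 3,
    flip_threshold: int = 8,
) -> ClusterPartition:
    """Spatial majority smoothing of a label field.

    Each round simultaneously relabels every cell for which some single
    foreign label is carried by strictly more than ``flip_threshold`` of
    its ``k`` spatial neighbors (defaults: 3 rounds, more than 8 of 15
    neighbors).  A tie between two foreign labels at the maximal count
    keeps the original label.
    """
    current = _label_array(labels).copy()
    cell_ids = labels.cell_ids if isinstance(labels, ClusterPartition) else None
    for _ in range(rounds):
        neighbor_labels = current[graph.neighbors]  # (N, k)
        new = current.copy()
        for u in range(current.size):
            own = current[u]
            vals, counts = np.unique(neighbor_labels[u], return_counts=True)
            foreign = vals != own
            if not foreign.any():
                continue
            fvals, fcounts = vals[foreign], counts[foreign]
            top = fcounts.max()
            if top > flip_threshold and (fcounts == top).sum() == 1:
                new[u] = fvals[np.argmax(fcounts)]
        if np.array_equal(new, current):
            break
        current = new
    return ClusterPartition(current, cell_ids)


def ari(a, b) -> float:
    """Adjusted Rand index between two partitions of the same cells."""
    la, lb = _label_array(a), _label_array(b)
    if la.size != lb.size:
        raise ValueError("partitions cover different cell sets")
    return float(adjusted_rand_score(la, lb))
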