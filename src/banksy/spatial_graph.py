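"""Spatial neighborhoods and the scale-invariant Gaussian envelope.

Each cell's microenvironment is its ``k`` nearest neighbors in physical
space (self excluded).  Weights over a neighborhood follow a Gaussian
envelope exp(-r_uv^2 / r_{u,vbar}^2) normalized to sum to 1, where the
length scale r_{u,vbar} is the distance to the cell's
floor(m*k_geom/2)-th nearest neighbor (1-based).  Anchoring the scale to
a neighbor-rank distance rather than an absolute length makes the
envelope invariant to uniform rescaling of the coordinates and adaptive
to local cell-density variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

__all__ = ["SpatialNeighborGraph", "EnvelopeWeights", "build_knn", "gaussian_envelope"]

_BRUTE_FORCE_MAX = 4096  # below this, exact all-pairs search with index tie-break


@dataclass
class SpatialNeighborGraph:
    """Ordered k-nearest-neighbor lists with distances and azimuths.

    ``neighbors[u]`` lists cell indices by ascending distance from u (ties
    broken by ascending cell index); ``azimuths[u, j]`` is the angle of
    neighbor j measured counterclockwise from the positive x-axis of the
    frame centered at u, in (-pi, pi].
    """

    neighbors: np.ndarray  # (N, k) int
    dists: np.ndarray      # (N, k) float, nondecreasing along axis 1
    azimuths: np.ndarray   # (N, k) float in (-pi, pi]
    k: int
    sample_constrained: bool = False

    @property
    def n_cells(self) -> int:
        return self.neighbors.shape[0]

    def to_edge_list(self):
        """Rows of (u, v, rank, distance, azimuth) for inspection/export."""
        rows = []
        for u in range(self.n_cells):
            for rank in range(self.k):
                rows.append(
                    (u, int(self.neighbors[u, rank]), rank + 1,
                     float(self.dists[u, rank]), float(self.azimuths[u, rank]))
                )
        return rows

    def write_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("u\tv\trank\tdistance\tazimuth\n")
            for u, v, rank, d, a in self.to_edge_list():
                fh.write(f"{u}\t{v}\t{rank}\t{d!r}\t{a!r}\n")


@dataclass
class EnvelopeWeights:
    """Per-cell normalized Gaussian envelope weights over the neighbor lists."""

    weights: np.ndarray        # (N, k), rows sum to 1
    reference_ordinal: int     # 1-based neighbor rank setting the length scale
    m: int                     # 1 for the mean kernel, 2 for the AGF


def _knn_single(coords: np.ndarray, k: int):
    """Exact kNN with deterministic (distance, index) tie-break."""
    n = coords.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} cells, got {n}")
    if n <= _BRUTE_FORCE_MAX:
        d = cdist(coords, coords)
        np.fill_diagonal(d, np.inf)
        idx = np.argsort(d, axis=1, kind="stable")[:, :k]
    else:
        # query a margin of extra candidates, then re-sort by (dist, index)
        # so boundary ties resolve identically to brute force
        extra = min(n - 1, k + 8)
        tree = cKDTree(coords)
        dd, ii = tree.query(coords, k=extra + 1)
        idx = np.empty((n, k), dtype=int)
        for u in range(n):
            cand = ii[u][ii[u] != u]
            dcand = np.linalg.norm(coords[cand] - coords[u], axis=1)
            order = np.lexsort((cand, dcand))
            idx[u] = cand[order][:k]
        dists = np.linalg.norm(coords[idx] - coords[:, None, :], axis=2)
        return idx, dists
    dists = np.take_along_axis(d, idx, axis=1)
    return idx, dists


def build_knn(coords: np.ndarray, k: int, sample_of=None) -> SpatialNeighborGraph:
    """Build exact k-nearest-neighbor lists under Euclidean distance.

    When ``sample_of`` is given, the search is restricted within each
    sample so neighborhoods never cross sample (e.g. tissue-slice)
    boundaries.  Any sample with <= k cells raises an error naming it.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if sample_of is None:
        idx, dists = _knn_single(coords, k)
        constrained = False
    else:
        sample_of = np.asarray(sample_of)
        idx = np.empty((n, k), dtype=int)
        dists = np.empty((n, k), dtype=float)
        for s in pd_unique(sample_of):
            members = np.flatnonzero(sample_of == s)
            if members.size <= k:
                raise ValueError(
                    f"sample {s!r} has {members.size} cells; need more than k={k}"
                )
            sub_idx, sub_d = _knn_single(coords[members], k)
            idx[members] = members[sub_idx]
            dists[members] = sub_d
        constrained = True
    delta = coords[idx] - coords[:, None, :]
    azimuths = np.arctan2(delta[..., 1], delta[..., 0])
    return SpatialNeighborGraph(
        neighbors=idx, dists=dists, azimuths=azimuths, k=k,
        sample_constrained=constrained,
    )


def pd_unique(values: np.ndarray):
    """Unique values in first-seen order (stable, unlike np.unique)."""
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def reference_ordinal(m: int, k_geom: int) -> int:
    """The 1-based neighbor rank anchoring the envelope length scale:
    floor(m * k_geom / 2).  For k_geom = 15, m = 1 this is the 7th
    nearest neighbor."""
    return (m * k_geom) // 2


def gaussian_envelope(
    graph: SpatialNeighborGraph,
    m: int,
    k_geom: int,
    reference: int | None = None,
) -> EnvelopeWeights:
    """Normalized Gaussian envelope weights over each cell's neighbor list.

    The unnormalized weight of neighbor v of cell u is
    exp(-r_uv^2 / r_{u,vbar}^2) with vbar the floor(m*k_geom/2)-th nearest
    neighbor of u (overridable via ``reference``).  Cells whose reference
    distance is zero (coincident points) fall back to uniform weights with
    a warning.
    """
    if m not in (1, 2):
        raise ValueError("m must be 1 (mean kernel) or 2 (AGF)")
    if graph.k != m * k_geom:
        raise ValueError(
            f"graph built with k={graph.k}, expected m*k_geom={m * k_geom}"
        )
    ref = reference_ordinal(m, k_geom) if reference is None else int(reference)
    if not 1 <= ref <= graph.k:
        raise ValueError(f"reference ordinal {ref} outside 1..{graph.k}")
    sigma = graph.dists[:, ref - 1]
    degenerate = sigma == 0
    safe_sigma = np.where(degenerate, 1.0, sigma)
    w = np.exp(-(graph.dists ** 2) / (safe_sigma ** 2)[:, None])
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} cell(s) have zero reference-neighbor "
            "distance; using uniform weights for them"
        )
        w[degenerate] = 1.0
    w /= w.sum(axis=1, keepdims=True)
    return EnvelopeWeights(weights=w, reference_ordinal=ref, m=m)
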