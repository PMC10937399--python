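"""PCA embedding of the augmented matrix and Leiden community detection.

Cells (columns of the augmented matrix) are the observations.  The feature
rows are already zero-centered by z-scaling and the lambda weights preserve
that, so no re-centering is applied before the singular-value decomposition.
Component signs are fixed by convention (largest-magnitude loading made
positive) so embeddings are reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .datamodel import ClusterPartition, RunConfig, SpatialDataset
from .features import AugmentedMatrix, augment_dataset, multisample_augment, zscale_rows

__all__ = [
    "Embedding",
    "ExpressionGraph",
    "reduce",
    "build_expression_graph",
    "cluster_graph",
    "run_banksy",
    "run_nonspatial",
    "BanksyResult",
    "cluster_at_resolutions",
    "match_cluster_count",
]


@dataclass
class Embedding:
    """Principal-component scores of cells (N x d) with explained variance."""

    scores: np.ndarray
    explained_variance: np.ndarray
    components: np.ndarray  # feature loadings, (n_features x d)

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]


@dataclass
class ExpressionGraph:
    """Union-symmetrized unweighted kNN graph over cells in embedding space."""

    adjacency: sp.csr_matrix  # symmetric boolean, no self-loops
    k_expr: int

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    def to_igraph(self) -> ig.Graph:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        edges = list(zip(coo.row.tolist(), coo.col.tolist()))
        return ig.Graph(n=self.n_cells, edges=edges)


def reduce(aug: AugmentedMatrix | np.ndarray, n_pcs: int = 20) -> Embedding:
    """Top-``n_pcs`` principal components of the cells.

    Deterministic up to component sign, which is fixed by making the
    largest-magnitude feature loading of each component positive.
    ``n_pcs`` greater than min(3p, N) is clipped with a warning.
    """
    values = aug.values if isinstance(aug, AugmentedMatrix) else np.asarray(aug)
    n_features, n_cells = values.shape
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    d_max = min(n_features, n_cells)
    if n_pcs > d_max:
        warnings.warn(f"n_pcs={n_pcs} clipped to {d_max}")
        n_pcs = d_max
    U, S, Vt = np.linalg.svd(values, full_matrices=False)
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    # sign convention: largest |loading| positive
    for j in range(n_pcs):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j] = -Vt[j]
    scores = (Vt * S[:, None]).T  # N x d
    explained = (S ** 2) / n_cells
    return Embedding(scores=scores, explained_variance=explained, components=U)


def build_expression_graph(emb: Embedding | np.ndarray, k_expr: int = 50) -> ExpressionGraph:
    """kNN graph over cells in embedding space, symmetrized by edge union,
    edges unweighted.  ``k_expr >= N`` is clipped to N-1 with a warning."""
    scores = emb.scores if isinstance(emb, Embedding) else np.asarray(emb)
    n = scores.shape[0]
    if k_expr >= n:
        warnings.warn(f"k_expr={k_expr} clipped to {n - 1}")
        k_expr = n - 1
    nn = NearestNeighbors(n_neighbors=k_expr).fit(scores)
    ind = nn.kneighbors(return_distance=False)  # self excluded for train queries
    rows = np.repeat(np.arange(n), k_expr)
    cols = ind.ravel()
    A = sp.csr_matrix((np.ones(rows.size, dtype=bool), (rows, cols)), shape=(n, n))
    A = (A + A.T).astype(bool)
    A.setdiag(False)
    A.eliminate_zeros()
    return ExpressionGraph(adjacency=A.tocsr(), k_expr=k_expr)


def cluster_graph(g: ExpressionGraph | ig.Graph, resolution: float, seed: int) -> ClusterPartition:
    """Leiden community detection under the resolution-parameterized
    (RB configuration) modularity objective, run to convergence.

    Identical (graph, resolution, seed) always yields identical labels;
    labels are canonicalized to 0..K-1 by decreasing cluster size.
    Disconnected components are handled independently by the optimizer.
    """
    graph = g.to_igraph() if isinstance(g, ExpressionGraph) else g
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,  # iterate until no improving move exists
    )
    labels = np.asarray(part.membership, dtype=int)
    return ClusterPartition(labels).relabel_by_size()


@dataclass
class BanksyResult:
    """Everything one embedding-and-clustering run produced."""

    partition: ClusterPartition
    embedding: Embedding
    expression_graph: ExpressionGraph
    augmented: AugmentedMatrix
    spatial_graph: object  # k_geom-neighbor SpatialNeighborGraph (None for nonspatial)
    config: RunConfig
    cell_ids: list[str] = field(default_factory=list)


def run_banksy(ds: SpatialDataset | list[SpatialDataset], config: RunConfig) -> BanksyResult:
    """The full pipeline: spatial graphs -> kernels -> z-scale -> augment ->
    PCA -> expression graph -> Leiden.

    A list of datasets (or a single dataset carrying ``sample_of``) runs in
    multisample mode: per-sample graphs, kernels and z-scaling, then
    column-wise concatenation of the augmented matrices before the shared
    PCA/clustering stage.

    At ``lambda_mix = 0`` the mean and AGF blocks carry exactly zero weight,
    so the pipeline reduces to nonspatial clustering of the z-scaled
    expression matrix; the zero-weighted blocks are skipped outright (an
    exact simplification — appending all-zero rows cannot change principal
    components) and :func:`run_nonspatial` is dispatched.
    """
    if config.lambda_mix == 0 and not isinstance(ds, list):
        return run_nonspatial(ds, config)
    multi = isinstance(ds, list) or (
        getattr(ds, "sample_of", None) is not None
        and len(set(np.asarray(ds.sample_of).tolist())) > 1
    )
    spatial_graph = None
    if isinstance(ds, list):
        aug, cell_ids, _ = multisample_augment(ds, config)
    elif multi:
        parts = [ds.subset_cells(ix) for _, ix in ds.split_by_sample()]
        order = np.concatenate([ix for _, ix in ds.split_by_sample()])
        aug, cell_ids, _ = multisample_augment(parts, config)
        # restore original cell order so outputs align with the input dataset
        inverse = np.argsort(order)
        aug.values = aug.values[:, inverse]
        cell_ids = [cell_ids[i] for i in inverse]
    else:
        aug, spatial_graph, _ = augment_dataset(ds, config)
        cell_ids = list(ds.cell_ids)
    emb = reduce(aug, config.n_pcs)
    graph = build_expression_graph(emb, config.k_expr)
    part = cluster_graph(graph, config.resolution, config.seed)
    part.cell_ids = cell_ids
    return BanksyResult(
        partition=part, embedding=emb, expression_graph=graph, augmented=aug,
        spatial_graph=spatial_graph, config=config, cell_ids=cell_ids,
    )


def run_nonspatial(ds: SpatialDataset, config: RunConfig) -> BanksyResult:
    """Conventional nonspatial clustering: z-scaled expression -> PCA ->
    expression graph -> Leiden, with no spatial features at all.  Serves as
    the lambda = 0 reference path."""
    C_z = zscale_rows(ds.expression)
    emb = reduce(C_z, config.n_pcs)
    graph = build_expression_graph(emb, config.k_expr)
    part = cluster_graph(graph, config.resolution, config.seed)
    part.cell_ids = list(ds.cell_ids)
    aug = AugmentedMatrix(values=C_z, lambda_mix=0.0, mu=config.mu, n_genes=ds.n_genes)
    return BanksyResult(
        partition=part, embedding=emb, expression_graph=graph, augmented=aug,
        spatial_graph=None, config=config, cell_ids=list(ds.cell_ids),
    )


def cluster_at_resolutions(result: BanksyResult, resolutions, seed: int | None = None):
    """Re-cluster an existing run's expression graph over a resolution grid
    (the graph and embedding are reused; only Leiden is re-run)."""
    seed = result.config.seed if seed is None else seed
    return {float(r): cluster_graph(result.expression_graph, float(r), seed)
            for r in resolutions}


def match_cluster_count(result: BanksyResult, n_clusters: int, resolutions, seed=None):
    """Partitions from a resolution scan whose cluster count matches the
    target (the way a user pins an ontological level).  Falls back to the
    partitions with the nearest cluster count if no resolution matches."""
    parts = cluster_at_resolutions(result, resolutions, seed)
    exact = [p for p in parts.values() if p.n_clusters == n_clusters]
    if exact:
        return exact
    best = min(abs(p.n_clusters - n_clusters) for p in parts.values())
    return [p for p in parts.values() if abs(p.n_clusters - n_clusters) == best]
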