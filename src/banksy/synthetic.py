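"""Synthetic spatial-omics datasets with known cell-type and domain truth.

The generator emulates the structure of a layered tissue: spatially
contiguous domains (striped layers by default, a cortical-layer analogue),
each with its own cell-type mixture.  At least one type is shared between
adjacent domains and one "dispersed" type is present everywhere, so domain
identity is a property of the neighborhood composition, not of any single
cell's transcriptome — the regime the lambda parameter is designed to
separate.  Counts are negative-binomial with type-specific means
(marker genes at a fold-change over a baseline), giving overdispersed
noise (variance > mean); gene-gene correlation is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import SpatialDataset

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate",
    "rotate_coords",
    "hexagonal_lattice",
    "default_mixtures",
]


def default_mixtures(n_domains: int = 3, n_types: int = 5) -> np.ndarray:
    """Domain x type mixing proportions for the standard layered scenario.

    Types 0..n_domains-1 are domain-enriched; the second-to-last type is
    shared between the first two domains; the last type is spatially
    dispersed, present in every domain at the same frequency.
    """
    if n_domains == 3 and n_types == 5:
        return np.array(
            [
                # t0    t1    t2    t3    t4 (dispersed)
                [0.55, 0.25, 0.00, 0.00, 0.20],
                [0.00, 0.25, 0.55, 0.00, 0.20],
                [0.00, 0.00, 0.00, 0.80, 0.20],
            ]
        )
    # generic fallback: each domain enriched for one type, last type shared
    mix = np.full((n_domains, n_types), 0.0)
    for d in range(n_domains):
        mix[d, d % (n_types - 1)] = 0.8
        mix[d, n_types - 1] = 0.2
    return mix / mix.sum(axis=1, keepdims=True)


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults define the standard test scenario."""

    n_cells: int = 1200
    layout: str = "striped_layers"  # striped_layers | blocks | annulus
    n_domains: int = 3
    n_types: int = 5
    mixtures: np.ndarray | None = None  # domains x types, rows sum to 1
    n_genes: int = 60
    n_markers_per_type: int = 8
    base_mean: float = 0.5       # NB mean of non-marker genes
    marker_fold: float = 6.0     # fold change of a type's marker genes
    dispersion: float = 2.0      # NB size theta; var = mu + mu^2/theta
    shared_type_shift: float = 0.0  # planted expression shift of the dispersed
                                    # type in the last domain (microenvironment
                                    # -driven subtype scenario when > 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mixtures is None:
            self.mixtures = default_mixtures(self.n_domains, self.n_types)
        self.mixtures = np.asarray(self.mixtures, dtype=float)
        if self.mixtures.shape != (self.n_domains, self.n_types):
            raise ValueError("mixtures must be n_domains x n_types")
        if np.any(self.mixtures < 0) or not np.allclose(self.mixtures.sum(axis=1), 1.0):
            raise ValueError("each domain's mixture must be nonnegative and sum to 1")
        shared = ((self.mixtures > 0).sum(axis=0) >= 2).any()
        if not shared:
            raise ValueError(
                "at least one cell type must be shared between two domains "
                "(otherwise domains coincide with types)"
            )
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")
        if self.n_markers_per_type * self.n_types > self.n_genes:
            raise ValueError("not enough genes for the requested marker sets")


@dataclass
class SyntheticTruth:
    """A generated dataset bundled with its ground-truth labels."""

    dataset: SpatialDataset
    true_type: np.ndarray
    true_domain: np.ndarray
    config: SyntheticConfig
    type_means: np.ndarray = field(default=None)  # types x genes NB means


def _domain_of_coords(coords: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    x, y = coords[:, 0], coords[:, 1]
    if cfg.layout == "striped_layers":
        return np.clip(np.floor(y).astype(int), 0, cfg.n_domains - 1)
    if cfg.layout == "blocks":
        nx = int(np.ceil(np.sqrt(cfg.n_domains)))
        col = np.clip(np.floor(x).astype(int), 0, nx - 1)
        row = np.clip(np.floor(y).astype(int), 0, int(np.ceil(cfg.n_domains / nx)) - 1)
        return np.clip(row * nx + col, 0, cfg.n_domains - 1)
    if cfg.layout == "annulus":
        r = np.hypot(x, y)
        return np.clip(np.floor(r).astype(int), 0, cfg.n_domains - 1)
    raise ValueError(f"unknown layout {cfg.layout!r}")


def _sample_coords(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    n = cfg.n_cells
    if cfg.layout == "striped_layers":
        # stripes of height 1 stacked along y; width 3 per stripe
        x = rng.uniform(0, 3.0, n)
        y = rng.uniform(0, cfg.n_domains, n)
        return np.column_stack([x, y])
    if cfg.layout == "blocks":
        nx = int(np.ceil(np.sqrt(cfg.n_domains)))
        ny = int(np.ceil(cfg.n_domains / nx))
        pts = rng.uniform(0, [nx, ny], size=(2 * n, 2))
        keep = _domain_of_coords(pts, cfg) < cfg.n_domains
        return pts[keep][:n]
    if cfg.layout == "annulus":
        r = np.sqrt(rng.uniform(0, cfg.n_domains ** 2, n))
        theta = rng.uniform(0, 2 * np.pi, n)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    raise ValueError(f"unknown layout {cfg.layout!r}")


def _type_means(cfg: SyntheticConfig) -> np.ndarray:
    """NB mean matrix (types x genes): baseline everywhere, marker genes of
    type t at marker_fold x baseline.  Marker sets are disjoint blocks."""
    means = np.full((cfg.n_types, cfg.n_genes), cfg.base_mean)
    for t in range(cfg.n_types):
        lo = t * cfg.n_markers_per_type
        hi = lo + cfg.n_markers_per_type
        means[t, lo:hi] *= cfg.marker_fold
    return means


def generate(config: SyntheticConfig) -> SyntheticTruth:
    """Draw a dataset: uniform cell placement within the layout's domains,
    types from each domain's mixture, negative-binomial counts from
    type-specific means.  Deterministic given the config seed."""
    rng = np.random.default_rng(config.seed)
    coords = _sample_coords(rng, config)
    domain = _domain_of_coords(coords, config)
    types = np.empty(config.n_cells, dtype=int)
    for d in range(config.n_domains):
        members = np.flatnonzero(domain == d)
        types[members] = rng.choice(config.n_types, size=members.size, p=config.mixtures[d])
    means = _type_means(config)
    mu = means[types]  # cells x genes
    if config.shared_type_shift > 0:
        # plant a small expression shift for the dispersed type in the last
        # domain: same type, different microenvironment-correlated state
        dispersed = config.n_types - 1
        mask = (types == dispersed) & (domain == config.n_domains - 1)
        lo = dispersed * config.n_markers_per_type
        hi = lo + config.n_markers_per_type
        mu[np.ix_(mask, range(lo, hi))] *= 1.0 + config.shared_type_shift
    theta = config.dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))  # var = mu + mu^2/theta
    ds = SpatialDataset(
        expression=counts.T.astype(float),  # genes x cells
        gene_ids=[f"g{j}" for j in range(config.n_genes)],
        cell_ids=[f"c{i}" for i in range(config.n_cells)],
        coords=coords,
    )
    return SyntheticTruth(
        dataset=ds, true_type=types, true_domain=domain, config=config,
        type_means=means,
    )


def rotate_coords(ds: SpatialDataset, theta: float) -> SpatialDataset:
    """Rigidly rotate coordinates about their centroid; expression untouched."""
    c = ds.coords.mean(axis=0)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    new_coords = (ds.coords - c) @ rot.T + c
    return SpatialDataset(
        expression=ds.expression,
        gene_ids=list(ds.gene_ids),
        cell_ids=list(ds.cell_ids),
        coords=new_coords,
        sample_of=None if ds.sample_of is None else ds.sample_of.copy(),
    )


def hexagonal_lattice(n_rows: int, n_cols: int, spacing: float = 1.0) -> np.ndarray:
    """Coordinates of a hexagonal (triangular) lattice, as in hex-packed
    capture-spot arrays.  Each interior point has 6 first-order neighbors at
    ``spacing`` and 12 second-order neighbors (6 at sqrt(3)*spacing, 6 at
    2*spacing) — 18 points within the second-order shell."""
    pts = []
    for r in range(n_rows):
        for c in range(n_cols):
            x = c * spacing + (r % 2) * spacing / 2.0
            y = r * spacing * np.sqrt(3) / 2.0
            pts.append((x, y))
    return np.asarray(pts, dtype=float)
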