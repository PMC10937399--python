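# Methods

## Model

A dataset is a gene × cell matrix `C ∈ R^{p×N}` (nonnegative, typically
normalized and log-transformed counts) plus 2-D positions `x_u`. For each
cell `u`, its microenvironment is the set `η_k(u)` of its `k` nearest
neighbors in physical space (Euclidean distance, self excluded). Over a
neighborhood, weights follow the normalized Gaussian envelope

    Γ_uv = exp(−r_uv² / r_{u,v̄}²) / Σ_w exp(−r_uw² / r_{u,v̄}²),

where `v̄` is the ⌊m·k_geom/2⌋-th nearest neighbor of `u` (1-based; the 7th
for the default k_geom = 15, m = 1). Anchoring the length scale to a
neighbor rank rather than an absolute distance makes the weights invariant
to uniform coordinate rescaling and adaptive to local density — coordinates
can be in any consistent unit.

Two kernels summarize the microenvironment per gene `q`:

* mean kernel (m = 1, over k_geom neighbors): `M_u^(q) = Σ_v g_v^(q) Γ_uv`;
* azimuthal Gabor filter (m = 2, over 2·k_geom neighbors):
  `G_u^(q) = | Σ_v g_v^(q) Γ_uv e^{iφ_uv} |`, with `φ_uv` the azimuth of
  `v` in `u`'s frame. The gradient estimate uses twice as many neighbors
  as the mean because estimating a gradient needs more data points than
  estimating a mean. The modulus discards the global phase, so `G` is
  invariant to rigid rotation of the sample; the complex sum is carried in
  two real (cosine/sine) accumulators.

Rows of `C`, `M`, `G` are z-scaled (zero mean, unit variance) and stacked:

    B = [ √(1−λ)·C_z ; √(λ/μ)·M_z ; √(λ/(2μ))·G_z ],  μ = 1.5.

With μ = 1.5 the squared weights satisfy `(1−λ) + λ/μ + λ/(2μ) = 1` for all
λ, so squared cell–cell distances in `B` are a convex combination of the
three blocks' distances (asserted symbolically with sympy and numerically
in the tests). `B` is then embedded by PCA (top 20 components by default)
and clustered by Leiden community detection (RB-configuration modularity,
run until no improving move exists) on a union-symmetrized, unweighted
k_expr = 50 nearest-neighbor graph in the embedding.

## Parameters

| parameter | default | meaning |
|---|---|---|
| λ (`lambda_mix`) | 0.2 / 0.8 | own-vs-neighborhood weight; 0 = nonspatial, 0.2 cell typing, 0.8 domain segmentation |
| `k_geom` | 15 | physical-space neighbors per cell (18 for hexagonal capture-spot lattices: the full second-order shell of 6 + 12 sites) |
| `k_expr` | 50 | embedding-space neighbors for the clustering graph |
| `n_pcs` | 20 | principal components retained |
| μ (`mu`) | 1.5 | normalization making the block weights convex |
| `resolution` | user-set | Leiden resolution; pinned either directly or by scanning a grid for a target cluster count |
| `seed` | user-set | single seed controlling all randomness in a run |

## Numerical and design choices

* **z-scaling** uses the population variance (divide by N); the convention
  is isolated in `zscale_rows` so the sample-variance dialect is a one-line
  change. Zero-variance rows are mapped to all-zeros with a warning.
* **kNN ties** are broken by ascending cell index, making graphs (and
  therefore the whole pipeline) deterministic even with coincident points.
  Coincident points that zero the envelope's reference distance fall back
  to uniform weights with a warning.
* **PCA** is computed by SVD without re-centering: the feature rows have
  exactly zero mean after z-scaling and the λ weights preserve that.
  Component signs follow the largest-magnitude-loading-positive convention.
  In multisample mode the concatenated matrix is only per-sample centered,
  a deliberate mirror of per-sample z-scaling.
* **AGF envelope reference**: the m = 2 envelope anchors on the
  ⌊2·k_geom/2⌋ = k_geom-th neighbor (the literal m = 2 reading); a
  `reference` override is exposed for the ⌊k_geom/2⌋ reading.
* **λ = 0** dispatches to the nonspatial path outright: the neighborhood
  blocks carry exactly zero weight and appending all-zero rows cannot
  change principal components, so skipping them is an exact simplification
  (verified label-identical in the tests).
* **Expression graph**: unweighted union-symmetrized kNN — the simplest
  contract consistent with "k neighbors in the embedding space". SNN
  weighting is a possible extension, not implemented.
* **Cluster labels** are canonicalized to 0..K−1 by decreasing size (ties
  by original label) for stable cross-run comparison.
* **Resolution** has no imposed default; the CLI requires it explicitly.
  `match_cluster_count` scans a user-given resolution grid and returns all
  partitions matching a target cluster count (falling back to the nearest
  count if none matches), which is how the synthetic benchmarks pin the
  ontological level.
* **HVG selection** ranks genes by variance of the (log-normalized)
  expression, descending, ties by original order — a deliberate
  approximation to mean–variance-trend dialects, documented as such.
* **Count-filter percentiles** use linear interpolation; fraction-based
  gene-prevalence thresholds use a ceiling ("at least 1% of cells").
* **NCC** uses the directed neighbor relation exactly as defined —
  `NCC[r, q]` = edges from reference cluster r into query cluster q,
  normalized by r's within-edges; reference clusters index rows. A
  reference cluster with no within-edges yields a NaN row with a warning.
* **Label smoothing** updates synchronously (order-independent): a cell
  flips to a foreign label carried by strictly more than `flip_threshold`
  of its k neighbors (defaults 8 of 15, 3 rounds); a tie between foreign
  labels keeps the original label.
* **Cluster consensus** maximizes total overlap via
  `scipy.optimize.linear_sum_assignment` on the contingency matrix;
  unmatched clusters of the second partition receive fresh labels.

## Synthetic data

The generator emulates a layered tissue (striped domains, a cortical-layer
analogue; block and annulus layouts are also available): cells placed
uniformly within stripes, each domain with its own cell-type mixture.
Defaults — chosen once as a realistic desk-scale scenario — are 1200
cells, 3 stripes (3 × 1 units each), 5 types, 60 genes. Type mixtures:
stripe 1 = {55% type 0, 25% type 1, 20% type 4}; stripe 2 = {25% type 1,
55% type 2, 20% type 4}; stripe 3 = {80% type 3, 20% type 4}. Type 1 is
shared between stripes 1–2 and type 4 is dispersed through all stripes, so
domain identity is not decodable from any single cell's transcriptome.
Counts are negative-binomial with size θ = 2 (variance = μ + μ²/θ, strongly
overdispersed), baseline mean 0.5, and 8 disjoint marker genes per type at
6× fold change. An optional `shared_type_shift` plants a small expression
shift in the dispersed type within one domain, a desk-scale analogue of
microenvironment-driven subtype splitting.

What the generator does **not** emulate: gene–gene correlation (no copula),
segmentation errors, spot mixing/contamination, imaging noise, or empirical
library-size distributions. Passing tests therefore demonstrate the
machinery's correctness and the λ mechanism's behavior under its intended
data-generating assumptions, not performance on any real tissue.

## Problem sizes and reproducibility

The test suite and the acceptance script run the full pipeline on 300-cell
and 1200-cell simulations (seconds per run), sizes at which the clustering
signal is comfortably above noise while the brute-force oracles (O(N²) kNN,
factorial assignment search, pair-counting ARI) stay exact and fast. All
randomness in a run flows from one integer seed (graph construction and
SVD are deterministic; Leiden receives the seed directly), so repeated runs
are byte-identical.

## Known limitations

* Only kNN neighborhoods (no radius or Delaunay policies) and 2-D
  coordinates; 3-D data are rejected rather than silently projected.
* Only the first azimuthal harmonic `e^{iφ}` is computed.
* Batch correction is an interface point (an externally corrected embedding
  can replace the PCA scores); no correction algorithm is implemented.
* The resolution parameter must be supplied or scanned; there is no
  automatic model selection for the number of clusters.
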