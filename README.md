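# banksy — spatial-omics clustering with neighbor-augmented features

Spatial transcriptomics assays (MERFISH, Slide-seq, Visium, STARmap, ...)
measure a gene × cell expression matrix together with each cell's physical
position. Two distinct questions are usually asked of such data: *what cell
types are present?* (cells of one type need not be near each other) and
*what tissue domains exist?* (spatially contiguous regions defined by their
neighborhood composition, often containing several cell types). This package
solves both with one algorithm, switched by a single mixing parameter.

## The method

Each cell *u*'s own expression vector is augmented with two spatial-kernel
summaries of its microenvironment:

* the **weighted neighborhood mean** over its k_geom nearest neighbors,
  `M_u^(q) = Σ_v g_v^(q) Γ_uv`, and
* the **azimuthal Gabor filter (AGF)**
  `G_u^(q) = | Σ_v g_v^(q) Γ_uv e^{iφ_uv} |` over its 2·k_geom nearest
  neighbors — the modulus of the first azimuthal Fourier harmonic of
  neighborhood expression, a rotation-invariant gradient sensor,

where Γ is a Gaussian envelope `exp(−r_uv² / r_{u,v̄}²)` normalized per cell,
with the length scale set by the distance to the ⌊m·k_geom/2⌋-th nearest
neighbor — making the weights scale-invariant and density-adaptive. After
per-row z-scaling, the three matrices are stacked into the
neighbor-augmented matrix

```
B = [ √(1−λ) · C_z ;  √(λ/μ) · M_z ;  √(λ/(2μ)) · G_z ]   ∈ R^{3p×N},  μ = 1.5
```

so the squared block weights sum to 1 for every λ ∈ [0, 1]. PCA (20
components) followed by Leiden community detection on a k_expr = 50
nearest-neighbor graph in the embedding yields the labels. λ = 0 reduces
exactly to conventional nonspatial clustering; λ ≈ 0.2 performs cell
typing; λ ≈ 0.8 performs domain segmentation.

Companion computations included: NCC (normalized cross-connectivity, the
ratio of cross- to within-cluster directed spatial-neighbor edges), metagene
scores, Hungarian cluster consensus, spatial label smoothing, ARI, standard
preprocessing (count filters, normalization, log1p, HVG selection), a
multisample concatenation mode, and a synthetic-data generator with
ground-truth cell-type and domain labels.

## Worked example

```python
from banksy import RunConfig, SyntheticConfig, ari, generate, run_banksy, run_nonspatial

truth = generate(SyntheticConfig(seed=0))          # 1200 cells, 3 domains, 5 types
ds = truth.dataset

typing = run_banksy(ds, RunConfig(mode="cell_typing", resolution=1.0, seed=0))
domains = run_banksy(ds, RunConfig(mode="domain_segmentation", resolution=0.5, seed=0))
nonspatial = run_nonspatial(ds, RunConfig(lambda_mix=0.0, resolution=0.5, seed=0, mode="custom"))

print(f"lambda=0.2: {typing.partition.n_clusters} clusters, "
      f"ARI vs true cell types  = {ari(typing.partition, truth.true_type):.3f}")
print(f"lambda=0.8: {domains.partition.n_clusters} clusters, "
      f"ARI vs true domains     = {ari(domains.partition, truth.true_domain):.3f}")
print(f"lambda=0.0: {nonspatial.partition.n_clusters} clusters, "
      f"ARI vs true domains     = {ari(nonspatial.partition, truth.true_domain):.3f}")
```

prints

```
lambda=0.2: 5 clusters, ARI vs true cell types  = 0.989
lambda=0.8: 3 clusters, ARI vs true domains     = 0.942
lambda=0.0: 5 clusters, ARI vs true domains     = 0.457
```

The same embedding machinery, at λ = 0.2, recovers the five simulated cell
types nearly perfectly; at λ = 0.8 it recovers the three tissue stripes —
including the correct domain assignment of the cell type that is present in
every stripe — while nonspatial clustering (λ = 0) can only find types and
therefore fails at domains.

The same pipeline is available from the shell:

```
banksy simulate --seed 0 --out sim/
banksy run --expr sim/expression.csv --coords sim/coords.csv \
           --mode domain --resolution 0.5 --seed 0 --out run/
banksy ari --labels-a run/labels.csv --labels-b truth_labels.csv
```

Subcommands: `preprocess`, `run`, `simulate`, `ncc`, `consensus`, `ari`,
`smooth`; every run writes a `manifest.json` with resolved parameters and
input digests.

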