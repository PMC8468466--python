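# Methods

## Model and procedure

The package integrates K omics layers measured in the same single cells by
a two-stage decomposition. Each layer `x_ijk ∈ R^{N_k × M}` is first reduced
to a common rank L by truncated SVD and projected through its left singular
vectors, `x_ℓjk = Σ_i u_ℓik x_ijk`; the projected layers are stacked into an
`L × M × K` tensor; higher-order SVD (HOSVD) of the tensor yields
orthonormal factor matrices per mode (feature `L × L`, cell `M × M'`, omics
`K × K`) and a core tensor `G`. Class structure is read out afterwards:
cell-mode factor columns are tested for coincidence with the known cell
classification by categorical regression (one-way F-test, BH-adjusted,
α = 0.01), feature-mode components are ranked by core energy restricted to
the coincident cell components, and the top component is back-projected to
one layer's original features, where a χ² statistic on standardized
loadings selects features (BH, α = 0.01).

Key properties and assumptions:

* **Missingness is neutral, not imputed.** Methylation is ternary (+1/−1
  observed, 0 missing); accessibility bins are only stored when observed.
  The truncated SVD operates on the sparse matrices directly; missing
  entries act as zeros, i.e. as absence of evidence. No feature filtering
  is applied.
* **Shared component indexing.** The tensor's first mode indexes
  "component ℓ of each layer" jointly. The mode-1 unfolding has nearly
  orthogonal rows (each row mixes the layers' rank-ℓ terms), so the mode-1
  factor is close to a permutation and back-projecting feature-mode
  component ℓ1 approximately returns the target layer's ℓ1-th left singular
  vector. The method therefore works best when the biological signal of
  interest occupies the same component index in every layer — in practice,
  when the classification is the dominant source of variation in each
  layer, as it is for developmental stage designs.
* **Layer weighting is implicit.** Layers are not rescaled relative to one
  another; the omics-mode factor absorbs scale differences. Layers with
  larger Frobenius norm (here methylation/accessibility after L1
  normalization) contribute more to the core energy.

## Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| `n_components` (L) | 10 | common SVD rank per layer |
| `alpha` | 0.01 | BH-adjusted threshold for both coincidence and feature selection |
| `n_top_components` | 1 | feature-mode components back-projected |
| `normalization` | `dataset1` | `dataset1`: L1 for methylation/accessibility + center+scale expression; `dataset2`: sparse layers untouched (safe when some cells have very few observations — L1 would give them enormous weight) |
| `call_threshold` | 0.5 | methylation level ≥ threshold → +1, else −1 (boundary counts as methylated) |
| `bin_size` | 200 nt | accessibility bin ≈ one nucleosome (147 nt core + linker) |
| `scale_method` | `sample_sd` | σ_ℓ1 in the χ² statistic: sample SD about the column mean (ddof = 1); `rms` (√mean u²) matches a mean-zero Gaussian null exactly |
| `n_neighbors` | 100 | UMAP neighborhood size; other UMAP settings at library defaults |

## Numerical choices

* Truncated SVD uses ARPACK Lanczos (`svds`) with a seed-derived start
  vector (tol 1e−8, iteration cap 1000); dense LAPACK SVD when
  L ≥ min(N, M) − 1 or the matrix is small. A near-degenerate trailing
  singular gap (relative < 1e−10) logs a warning — the retained subspace is
  then not unique — but does not fail.
* Sign convention: every singular/factor column is flipped so its
  maximum-magnitude entry is positive (ties: first index), giving
  reproducible output across runs and solvers.
* HOSVD mode-n matricization puts mode n on rows and the remaining modes in
  ascending order on columns. The cell-mode factor keeps
  M' = min(M, L·K) columns (the unfolding rank bound); with the
  corresponding economy core the reconstruction is still exact to
  numerical precision.
* Coordinates are 0-based half-open internally; site files on disk are
  1-based and converted on read. Features are ordered lexicographically by
  chromosome, then numerically by position.
* Zero-variance cell-mode vectors get p = 1 by convention (never selected);
  cells with zero observations are kept as all-zero columns with a warning
  and rejected by L1 normalization with an explicit error.
* Tolerances asserted in tests: 1e−10 relative for normalization moments
  and norm conservation, 1e−8 for reconstruction/orthonormality, 1e−6 for
  agreement with dense SVD oracles.

## Synthetic data: what it emulates and what it does not

`simulate_matrices` / `generate_multiomics` produce a stated world chosen
to mirror the regime the method targets — ordered developmental stages
whose progression dominates every omics layer:

* 300 cells in 3 equal classes interpreted as stages with scores
  t ∈ {−1, 0, +1}; 2000 genes, 50,000 methylation sites, 50,000
  accessibility bins (one candidate site per 200-nt bin).
* Expression: Gamma-Poisson counts (dispersion r = 2), log-normal gene
  means (σ = 1.5) calibrated so the expected nonzero fraction is 0.28.
  50 planted markers form a curated panel: base mean 8 (log-sd 0.25),
  stage-dependent factor `exp(2 · g · t)` with random sign g, renormalized
  per class so total marker expression is stage-independent (stages change
  marker composition, not mass — this keeps class signal out of the
  mean-profile component, which in real data is similarly dominated by
  stage-independent housekeeping expression).
* Methylation: per-(cell, site) observation probability 0.03; levels are
  Beta draws around per-site methylation probabilities; 30% of sites
  follow `sigmoid(2 · g · t)` — the genome-wide
  demethylation/remethylation waves that move a large share of
  developmental methylomes.
* Accessibility: observation probability 0.05, values 1 + Poisson(rate),
  15% of bins with stage-dependent rates, balanced per class.
* Effect size 2.0 scales every planted shift; effect 0 gives an exactly
  class-free null world.

Not emulated: read-level chemistry, CpG/GpC context, chromosomal
autocorrelation of methylation, doublets, batch effects, cell-cycle
variation, and unordered (non-developmental) class structure. A green
recovery test therefore establishes that the pipeline recovers a dominant
monotone axis and its markers at realistic sparsity — not that it would
resolve subtle unordered subpopulations.

## Design decisions taken where the design was open

* Methylation call threshold (how continuous levels map to
  methylated/unmethylated) defaults to 0.5 with "≥" counting as
  methylated; it is a configuration option since upstream callers differ.
* σ_ℓ1 estimation subtracts the mean (sample SD); the zero-mean `rms`
  variant is available. With many strong features the sample SD is
  inflated by the signal itself, which makes selection conservative — an
  intrinsic property of standardizing by a scale estimated on all features.
* Back-projection targets the expression layer by default; the operation
  is layer-generic and any layer can be chosen.
* Cell alignment across layers uses the intersection of cell IDs in the
  first (expression) layer's order; cells missing from any layer are
  dropped, never imputed.
* The CLI persists intermediate artifacts as MatrixMarket bundles, `.npz`
  arrays and TSV reports so every stage can run standalone.

## Known limitations

* The cross-layer index-sharing described above means class structure
  buried below each layer's leading components (weak or unordered effects)
  is unlikely to be ranked first; inspecting `component_ranking_` and the
  full association table is advised before trusting the default top-1
  back-projection.
* Expression centering densifies that layer; this is fine for ~10⁴–10⁵
  genes but the sparse layers must never be centered.
* The χ² null (Gaussian loadings) is approximate; p-values are used as
  ranked scores with FDR control rather than as literal tail
  probabilities.
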