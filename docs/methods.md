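# Methods

This note documents the models, defaults, and numerical choices behind
`costack`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate model

All images and point sets live in named 2-D frames with 0-based pixel
coordinates, origin top-left, `x` along columns, `y` along rows, and
half-open bounds: a frame of shape `(H, W)` contains points with
`0 ≤ x < W`, `0 ≤ y < H`, and the point `(x, y)` belongs to pixel
`(floor(y), floor(x))`. Centroids are reported at pixel centres
(`index + 0.5`). Physical pitch is carried as `microns_per_pixel`
metadata; distances given in µm in configs (expansion radius, match
radius) are converted once at stage entry. The common frame is the H&E
frame; every operation that combines two inputs refuses frames that
disagree.

## Registration (thin-plate spline)

Given landmark pairs `(sᵢ, tᵢ)` the fitted map is
`f(x) = A[1, x, y]ᵀ + Σᵢ wᵢ U(‖x − sᵢ‖)` with `U(r) = r² log r`, solved
from the standard augmented linear system with side conditions
`Σ wᵢ = 0`, `Σ wᵢ sᵢ = 0`. Regularisation adds `λI` to the kernel block:
`λ = 0` interpolates the landmarks exactly, larger λ trades misfit for
bending energy; the training residual is non-decreasing in λ (tested).
Degenerate inputs (fewer than 4 pairs, duplicated or collinear sources,
detected via the smallest singular value of the centred source matrix at
relative tolerance 1e-8) are rejected rather than solved unstably.

The inverse map, needed to pull a label mask from one frame into another
by nearest-neighbour resampling, is a second TPS fitted with the landmark
roles swapped. This is exact for affine maps and accurate to well below a
pixel for the smooth, small-amplitude deformations this pipeline
addresses; it is not a numerical inversion and will degrade for violent
warps, which are rejected anyway by a fold check (non-positive Jacobian
determinant of the forward map on a coarse grid).

Mask warping samples target pixel centres through the inverse map and
copies the nearest source pixel's label, so labels are preserved as a set
except for cells warped outside the target frame.

## Synthetic same-section tissue

The generator emulates the statistical structure the analysis assumes,
not the optics of any instrument.

**Geometry.** Cell centres are a jittered grid (jitter ±30% of spacing),
which is collision-free by construction; cell outlines are the Voronoi
cells of those centres (bounded by mirroring across the canvas edges),
clipped to the canvas, and shrunk about their centroid to the type's mean
cell radius (at most 92% of the Voronoi cell, leaving inter-cell gaps).
The nucleus is the cell polygon scaled by the nucleus/cell radius ratio,
hence strictly inside the cell. A capacity check rejects configurations
with `n_cells × mean cell area ≥ 0.7 × canvas area`.

**Regions.** The tumour region is a rectangle occupying the configured
fraction of the canvas width; cells are labelled by centroid membership.

**Molecules.** For each gene–protein pair with target rank correlation
ρ_s, latent standard normals `(z₁, z₂)` are drawn with Pearson parameter
`r = 2 sin(π ρ_s / 6)`, the exact inverse of the Gaussian-copula
Spearman formula, so the *latent* rank correlation equals ρ_s. Transcript
counts are NB quantiles `NB⁻¹(Φ(z₁); μ_{t,g}, θ)` (type-specific mean μ,
dispersion θ; variance μ + μ²/θ), then zero-inflated: with probability
`dropout[g]` the count is set to 0. Protein values are log-normal
quantiles `m_{t,c} · exp(σ z₂)`. The *observable* Spearman between count
and protein is attenuated below ρ_s by count discreteness/ties and by
dropout; tests therefore compare against a Monte-Carlo oracle that
samples the same generative equations directly (10⁵ draws) rather than
against ρ_s itself.

**Rendering.** Counts are scattered uniformly inside the cell polygon
(rejection sampling), plus uniform background spots at
`background_rate` per px². Protein channels are per-cell-constant fills
over the cell polygon plus i.i.d. Gaussian pixel noise (clipped at 0);
DAPI is rendered on nuclei; the membrane channel gets a 1.5× boundary
highlight. Because per-cell aggregation averages over hundreds of pixels,
pixel noise barely perturbs per-cell values, which is the property the
correlation analysis relies on.

**Discrepant segmentations.** Mask A mimics nuclear expansion: true
nuclei rasterised and grown by `expand_px` with collision-limited
nearest-seed assignment. Mask B mimics membrane segmentation: true cell
polygons eroded by `shrink_px` (cells erased entirely by the erosion are
dropped and logged). Both carry true cell ids.

**Deformation.** Each modality frame is displaced from the common frame
by a small affine part (rotation about the canvas centre + translation)
plus Gaussian radial bumps, normalised so the peak displacement equals
the configured amplitude (the normalisation grid is ~4 px, far finer than
the bump scale, and a 0.1% safety margin makes the amplitude a strict
upper bound). Fields that fold (non-positive Jacobian on a 32×32 grid)
are rejected. Landmark pairs are a regular grid mapped through the field,
with every 5th pair held out for registration QC.

**Defaults** (`simulate.default_config`): 512×512 px canvas at
0.5 µm/px, 450 cells, five cell types (tumour 40%, T 20%, B 10%,
macrophage 10%, stromal 20%), nucleus/cell radii 5/9 px, a 12-gene panel
with 10 gene–protein pairs named after a lung immune panel
(CDH1–ECad, KRT15–CK, MS4A1–CD20, CD3E–CD3, CD4–CD4, CD8A–CD8,
CD68–CD68, CD14–CD14, FCGR3A–CD16, MKI67–Ki67, plus unpaired PTPRC and
COL1A1), NB mean 16 in expressing types vs 1.2 baseline with dispersion
2, pair targets ρ_s = 0.8 → 0.3 and dropout 0 → 0.6 across the pairs,
protein log-sd 0.25, tumour fraction 0.35, deformation amplitude 6 px at
scale 128 px, background 10⁻⁴ spots/px². These are stated in the config
object, not hard-coded downstream; any YAML config can override them.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: optics (PSF, autofluorescence,
cycle-to-cycle artifacts), segmentation errors other than uniform
over/under-growth, spatially correlated expression programs, 3-D tissue,
batch effects, and antibody cross-reactivity (the mechanism behind
real-world low-correlation pairs). The generator's cells are convex and
near-regular; real morphology is far more varied.

## Integration rules

Transcripts map to the label under `(floor(y), floor(x))`; label 0 and
out-of-frame points count as unassigned, and
`assigned + unassigned = total` always holds. Intensity aggregation is
the exact per-cell pixel mean (implemented with bincount accumulation;
tested against a per-pixel oracle to 1e-10). Region assignment uses the
cell centroid, with overlapping polygons resolved in favour of the
smallest (logged). Filters are applied in pipeline order: ROI crop →
zero-transcript exclusion (min total ≥ 1) → analysis-specific filters
(the ≥ 20-count rule before clustering; the DAPI floor before proteomic
gating). In the full pipeline, intensities are aggregated in the SP
frame (masks warped into the SP frame through the inverse TPS) so the
protein pixels are never resampled.

## Segmentation comparison

Matching is greedy mutual-nearest-neighbour on centroid distance with a
cap (default 15 µm): near-optimal for well-separated cells, intrinsically
one-to-one, symmetric in the two tables, and deterministic
(distance-then-lowest-id ordering). The Hungarian algorithm was
deliberately not used — for this geometry it changes almost nothing and
costs O(n³). Per-gene inter-segmentation agreement is Spearman over
matched count pairs with average ranks; genes constant in either
segmentation are reported as missing rather than forced to a number.

## Correlation and differential correlation

Spearman throughout (average ranks for ties), which is invariant under
strictly increasing transforms of either variable — so background scaling
or exposure differences in intensities do not move ρ. Pairs with n < 3 or
a constant vector report a missing ρ with a reason. Dropout is the
fraction of cells with zero count among the cells entering the
correlation. The dropout-vs-ρ trend across pairs is itself a Spearman.

Fisher's Z compares regional correlations:
`z = (atanh ρ₁ − atanh ρ₂) / √(1.06/(n₁−3) + 1.06/(n₂−3))`, two-sided
normal p, significant iff p < α (default 0.05, raw; a Benjamini–Hochberg
flag is available but off by default). The 1.06 factor is the Fieller
variance correction appropriate for rank correlations. The resulting test
is approximately calibrated and mildly conservative: measured type-I
error at α = 0.05 is ≈ 0.048 at ρ = 0.3, n = 100 per region and ≈ 0.043
at ρ = 0 (10⁴ null replicates; see the calibration test and acceptance
script, which use 2 × 10³).

## Annotation

Marker rescaling is piecewise linear — `[min, gate] → [0, 0.5]`,
`[gate, q99] → [0.5, 1]`, clipped at the 99th percentile — so positivity
(`raw > gate` ⇔ `rescaled > 0.5`) is preserved exactly and the gating
tree can use the fixed threshold 0.5 everywhere. Gates outside the
observed range are allowed with a warning (all-positive/all-negative
markers occur in practice). The gating tree is fully user-specified
config (marker, relation, children); the default tree gates tumour by
PanCK, immune by CD45, then T/B/macrophage by CD3/CD20/CD68.

kNN label transfer takes the majority among k = 15 Euclidean nearest
reference points (k matching the neighbour count used for clustering);
vote ties break by smaller mean neighbour distance, then lexicographic —
fully deterministic. The reference embedding is an input artifact; the
pipeline fabricates one by sampling expression profiles from the
generator's type profiles and projecting with PCA (10 components, full
SVD for determinism), standing in for an external reference atlas
embedding, which is out of scope.

Concordance is computed only on cells matched across the two
segmentations (the same-section design makes cell-level matching
meaningful); per class, Jaccard = |A ∩ B| / |A ∪ B|, undefined (NaN) for
a class absent from both arms, alongside the full confusion table.

## Clustering

Counts (cells with total ≥ 20) are scaled per cell to a common target sum
and log1p-transformed — this preserves within-cell gene ranks (tested).
The kNN graph uses cosine distance (k = 15), edge weight = cosine
similarity, symmetrised by union keeping the larger weight; zero-norm
rows are an error naming the cell. Community detection is seeded Louvain
(networkx), with communities relabelled by smallest member node so a
fixed seed yields a fixed partition. Resolution defaults to 1.0 and is
configurable; modularity optima on kNN graphs of diffuse blobs sit finer
than "one community per blob", so recovering a small number of broad
programs can warrant a coarser resolution (the two-cluster recovery test
uses 0.5). Joint ST+SP embedding is deliberately not implemented: with
an order of magnitude fewer protein features the joint space is dominated
by ST, so the pipeline annotates each modality independently and compares
labels instead. UMAP is available as a pluggable embedding wrapper but is
not part of the deterministic default run.

## Determinism and problem sizes

Every stochastic operation draws from `numpy.random.default_rng` seeded
by `(config seed, operation tag)`; `run-all` logs the seed and a SHA-256
config hash, and two runs with one seed produce byte-identical outputs
(tested). Default problem sizes — 450 cells for the full pipeline, 5000
cells for correlation recovery, 2000 replicates for Fisher-Z calibration,
10⁵ draws for the Monte-Carlo oracle — were chosen so every quantity's
sampling error is comfortably below the tolerance being checked while the
whole suite stays fast on a single CPU.

## Known limitations

- The inverse-by-swapped-fit TPS is approximate for strong deformations;
  the fold check guards validity, not accuracy, at high amplitude.
- Mutual-NN matching drops cells whose counterpart is closer to another
  cell (no global assignment), and the distance cap leaves edge cells
  unmatched by design.
- The gating and label-transfer accuracy figures hold for the generator's
  well-separated type profiles; overlapping real-world profiles will be
  harder in ways the synthetic tests do not measure.
- Transcript assignment is by spot centre; spot extent and subcellular
  compartment are ignored.
- No intensity background subtraction is performed (assumed done
  upstream by the acquisition software).
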