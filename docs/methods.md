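# Methods

This note documents the models, numerical choices and limitations behind
`hemorph`, stage by stage. Everything quantitative asserted here is
computed by the test suite or by `scripts/acceptance.py`.

## Stain model and normalization

Bright-field H&E obeys Beer–Lambert attenuation per channel:
`I_c = I0_c · 10^(−OD_c)`, with `OD = S · w`, where `S` is a 3×3 matrix of
unit optical-density vectors (columns: hematoxylin, eosin, residual) and
`w` the per-pixel stain concentrations. The default `S` uses the canonical
published H&E vectors, hematoxylin (0.650, 0.704, 0.286) and eosin
(0.072, 0.990, 0.105), each renormalized; the residual column is their
unit cross product. `OD = log10(I0 / max(I, 1))` with `I0 = 255`; the
`max(I, 1)` floor caps the OD of fully absorbed pixels at `log10(255) ≈
2.41`. Deconvolution is `w = S⁻¹ · OD`; small negative concentrations are
clipped to zero in the returned channels (concentrations are physical)
while the raw values are retained so that `S · w_raw` reconstructs the OD
exactly (round-trip error < 1e-9 on random concentration fields).
Non-negative matrix factorization is deliberately not offered: the linear
transform is non-iterative, and NMF has no accuracy advantage for
two-stain brightfield material.

Stain normalization is per-channel monotone histogram specification
against one reference ("gold standard") tile: a gray level `g` with
left-continuous empirical CDF `p = P(X < g)` maps to the reference
channel's type-1 `p`-quantile, computed in exact integer arithmetic so the
map is an exact fixed point on the reference itself and idempotent to one
gray level. The left-continuous convention sends a degenerate
(single-valued) channel to the reference *minimum*, i.e. the darkest
plausible match rather than the brightest.

**Choice of reference.** Quantile matching maps the input's darkest
quantiles onto the reference's darkest quantiles. If the reference
contains proportionally *fewer* nuclear (dark) pixels than an input tile,
the input's dimmest nuclei land on reference background values and are
washed out — we observed segmentation recall dropping from ≥ 0.97 to 0.84
on some synthetic tiles with a sparser reference. The shipped synthetic
reference is therefore a well-stained, highly cellular tile (130 nuclei
per 512², fixed seed), mirroring how a pathologist picks a gold-standard
section. Users supplying their own reference should pick one at least as
cellular as their typical material. Normalization is applied per tile (one
quantile map per tile against the one global reference).

## Segmentation

**Thresholding.** The hematoxylin channel is quantized to 256 bins over
its own range and cut at the threshold minimizing intra-class variance
(equivalently maximizing between-class variance). For integral histograms
the argmax is computed in exact integer arithmetic with ties broken to the
smallest cut — exact ties do occur (e.g. near-symmetric histograms) and
floating point cannot order them reliably; the test suite checks exact
agreement with an independent rational-arithmetic exhaustive search.
Components are 4-connected; components outside [`min_area` = 40 px²,
`max_area` = 5000 px²] (plausible nuclear areas at 20×, ~0.5 µm/px) are
discarded, and the size filter is re-applied after refinement.

**Intensity refinement.** Each blob's intensity sample is fit with
mixtures of 1..3 Gaussians by EM (deterministic initialization: quantile
means, uniform weights, shared variance; 200 iterations; non-convergence
falls back to fewer components). The component count is chosen by BIC. A
split is accepted only if every adjacent pair of sorted component means is
separated by more than `gmm_separation` = 2.0 pooled standard deviations;
closer components are merged first. Blobs under `gmm_min_pixels` = 100 are
never split (a mixture fit on fewer pixels is unstable). An accepted split
is realized spatially by per-pixel maximum-responsibility assignment
followed by 4-connected relabeling; slivers below `min_area` are dropped.

**Geometric refinement.** Solidity (area / convex-hull area) below
`solidity_threshold` = 0.96 triggers concavity splitting: boundary points
are scored by their distance below the convex hull, the deepest point of
each contiguous run with depth ≥ `concavity_depth_min` = 2 px is a
concavity candidate, and the closest candidate pair whose connecting chord
lies inside the blob defines the cut; the procedure recurses until every
part passes the solidity test or no valid pair remains. When only one
concavity is visible (the far side of a neck can be shallower than the
depth floor), the cut runs from the deepest concavity to the nearest valid
boundary point on the opposite side — the standard single-concavity
fallback. The defaults were set jointly: rasterized convex nuclei (discs,
2:1 ellipses) measure solidity ≈ 0.98, while two overlapping discs at
center distance 1.5 r measure ≈ 0.95, so 0.96 separates the two cases;
necks between touching nuclei at the radius scale of this material
(r ≈ 6–10 px) are only 2–3 px deep, so a 3 px depth floor would miss most
of them, and 2 px is safe because only blobs that already failed the
solidity gate are examined for concavities. On synthetic tiles with 30%
of nuclei planted as touching pairs, ≥ 80% of pairs split into two
detections across seeds (typically 87–100%), with overall recall and
precision ≥ 0.95.

Refinement only ever removes or partitions foreground (cut chords are one
pixel wide), never merges or grows it.

## Morphometry and cellularity

Features per nucleus: unweighted centroid, area, perimeter, eccentricity,
solidity (via `skimage.measure.regionprops`), mean and population SD of
the hematoxylin concentration. Cellularity is `1 / A_i` where `A_i` is the
area of nucleus i's Voronoi region clipped to the tile rectangle. The
tessellation is computed exactly (polygon clipping, not rasterization) by
augmenting the centroids with their mirror images across the four tile
edges, which makes every original region finite and exactly equal to the
true Voronoi region intersected with the rectangle; clipped areas
partition the tile (sum = W·H to machine precision). Boundary cells are
clipped rather than dropped so every nucleus has a cellularity value.
Duplicate centroids are perturbed by +0.5 px in x (logged). Cellularity is
computed per block from the block's owned centroids and pooled per tissue.

The feature panel is intentionally compact — it covers the two features
used downstream for subtyping (nuclear area and cellularity) plus standard
shape/intensity descriptors; `extract_features` is the extension point for
a larger panel.

## Equal-weight cohort normalization

For each feature: (i) each tissue is an empirical density; (ii) all
tissues' values are pooled; (iii) the pooled distribution is re-binned at
its 0, 1/B, …, 1 type-1 quantiles (B = 10 by default, keeping the
subtyping vector at 2 × 10 dimensions), which guarantees per-bin pooled
counts differ by ≤ 1 when values are distinct; duplicate edges from
heavily tied data are collapsed with a logged reduction of B; (iv) each
tissue is remapped to a length-B probability vector (half-open bins, last
bin closed, out-of-range values clamp to the end bins so frozen binnings
can score new data). Multiple sections per patient are averaged
elementwise. The construction is purely rank-based: any strictly monotone
transform applied jointly to pooled and tissue values leaves the vectors
unchanged. Raw histograms are used without kernel smoothing — with ~10³
cells per tissue and B = 10, bin occupancies are well populated and
smoothing would only blur the subtype signatures.

## Consensus subtyping

Patients are points in R^(2B) (concatenated normalized area and
cellularity distributions). For each candidate K (default scan 2..8), 100
resamples each draw 80% of patients without replacement and k-means
cluster them (n_init = 10, seeded); consensus(i,j) = co-clustered /
co-selected. Final labels cut average-linkage hierarchical clustering of
1 − consensus at K. K is selected by the PAC-style ambiguity score — the
fraction of off-diagonal consensus entries in (0.1, 0.9) — with ties
broken to the **largest** tied K: merging two well-separated subtypes is
reproduced identically in every resample, so coarser merges are exactly as
unambiguous as the true partition and a smallest-K tie rule would
systematically under-segment. The ordered consensus matrix is also emitted
for the usual qualitative heatmap inspection.

## Survival

Kaplan–Meier: `S(t) = Π_{tᵢ ≤ t} (1 − dᵢ/nᵢ)` over distinct event times;
patients censored at an event time are still at risk for that event
(deaths-before-censorings tie convention). Log-rank: observed minus
expected events in group A accumulated over pooled event times with the
hypergeometric variance; the squared sum over the summed variance is
referred to χ²₁. Zero total variance returns (0, 1). The implementation is
cross-checked against lifelines and against naive risk-set enumeration;
type-I error is 0.05 within binomial error over 1000 null simulations and
power ≥ 0.9 at hazard ratio 2 with 200 per group. The per-subtype analysis
compares more-intensive vs less-intensive treatment groups within each
recovered subtype; no covariate adjustment (Cox or otherwise) is offered.

## Synthetic data: what it emulates and what it does not

**Tiles.** Elliptical nuclei with lognormal equivalent radius
(median 8 px, σ_log = 0.3 — realistic at 20×), axis ratio uniform in
[1, 2], per-nucleus hematoxylin OD ~ N(0.7, 0.15) (wide chromatin
variation is the central difficulty of thresholding real material),
within-nucleus chromatin texture (σ = 0.08 OD), a uniform eosin background
(0.25 OD), Beer–Lambert rendering through the same default basis used for
deconvolution, and Gaussian pixel noise (σ = 4 gray levels). A configured
fraction of nuclei is planted as touching pairs: both members share the
axis joining their centers at distance 0.85 (a₁ + a₂), producing a single
thresholded blob with a concave neck. Ground truth (label mask, centers,
areas, pair membership) is returned with the tile. A basis-perturbation
option exists for robustness experiments.

Not emulated: necrosis/apoptosis textures, tissue folds, out-of-focus
regions, anisotropic illumination, and spatially structured chromatin
texture.
Passing tests therefore demonstrate correctness of the pipeline's logic
and its behavior under controlled noise/overlap — not performance on real
whole-slide material, where heterogeneous fixation, staining and section
thickness push the accuracy of any thresholding-based recipe well below
the synthetic figures.

**Cohorts.** Five planted subtypes mirror the qualitative structure of the
motivating study: high / low / medium cellularity, high cellularity with
pleomorphism (area σ_log 0.6 vs 0.25), and extreme-high cellularity
(cellularity median 1.2×10⁻³ px⁻², the highest). Patients carry a
lognormal random effect (σ = 0.1) on their subtype medians, contribute 1–2
sections of 1000 cells each, and 20 patients per subtype by default
(a cohort of 100, the scale typical of single-institution histology
cohorts). Survival is exponential with baseline hazard ln 2 / 14.6 months
(the canonical GBM median survival); censoring is an independent
exponential at 0.01/month (~15–20% censored). Treatment (more- vs
less-intensive) is assigned by balanced permutation within subtype. Only
the extreme-high-cellularity subtype has a treatment effect, hazard ratio
0.05 for the more-intensive arm. This plant is deliberately strong, in the
same spirit as a 10σ cluster-separation plant: at 10 patients per arm
under this censoring, log-rank power at α = 0.05 is ~0.5 for HR 0.3 but
≥ 0.99 for HR 0.05, so only the strong plant makes end-to-end detection
informative about the pipeline rather than about small-sample test power.
The test's operating characteristics themselves are measured separately
under realistic effect sizes. The end-to-end check flags subtypes at
Bonferroni-corrected α (0.05/K) and additionally requires the planted
subtype to carry the smallest p-value: with four null subtypes, raw
α = 0.05 would flag a false positive on roughly a quarter of runs by
chance.

## Block decomposition

Images are partitioned into `block_size` (default 1024, ≥ 64) square
blocks, edge blocks truncated, so the union covers each pixel exactly
once. Each block is segmented on a window expanded by `margin` = 50 px of
context (≥ the largest plausible nucleus diameter); a nucleus is owned by
the block containing its centroid, and repeated detections from
neighboring windows are deduplicated by rounded global centroid. Blocks
are independent work units; aggregation is order-independent. Individual
block failures are logged and skipped; a run aborts if more than 10% of a
tissue's blocks fail. Every run writes a manifest (software version,
config hash, seed, selected K) beside its outputs, and identical
config + seed reproduces byte-identical CSV outputs.

## Problem sizes used in the shipped checks

The test suite and acceptance script use 512² tiles with 100 nuclei (the
unit at which the block machinery is exercised with 128-px blocks),
100-patient cohorts (20 per subtype), 1000 null and 200 alternative
log-rank simulations, and 20 cohort seeds for subtype recovery. These
sizes give tight Monte-Carlo error on every reported rate while keeping a
full run in the minutes range on one CPU.

## Known limitations

- Global per-tile histogram matching is composition-sensitive; a tile
  whose true foreground fraction exceeds the reference's will lose its
  dimmest nuclei (mitigated by the cellular-reference rule above, not
  eliminated).
- Otsu thresholding assumes a bimodal hematoxylin histogram per block;
  blocks that are entirely background yield noise components that the
  area filter must remove.
- The GMM split assigns pixels by intensity only; two merged nuclei with
  identical chromatin content are separable only by the convexity path.
- Voronoi cellularity treats block borders as tile borders (cells clipped
  per block), slightly inflating cellularity for border nuclei relative to
  a whole-slide tessellation.
- PAC-based K selection with largest-tie-breaking can overestimate K if
  the candidate range extends far beyond the true K and resampling noise
  vanishes; with the default resampling (80%, 100 resamples) this was not
  observed over 20 seeds.
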