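# hemorph

Block-parallel morphometric analysis of H&E-stained tissue sections:
from raw RGB tiles to nuclear segmentation, per-cell features, cohort-level
distribution normalization, consensus subtyping, and survival comparison.

## Who this is for

Computational pathology groups that want a transparent, fully tested
reference implementation of the classic whole-slide morphometry recipe used
to subtype tumors (the motivating application is glioblastoma multiforme,
where nuclear size and cellularity separate tissue sections into subtypes
with different responses to therapy intensity). Every stage runs on
ground-truthed synthetic H&E tiles and cohorts generated by the package
itself, so the whole pipeline is verifiable without any external data.

## The method

1. **Stain normalization.** Each tile is normalized against one
   "gold standard" reference tile by per-channel monotone quantile mapping
   (histogram specification), removing staining heterogeneity.
2. **Color deconvolution.** Intensities are converted to optical density
   (Beer–Lambert, `OD = log10(I0 / I)`), where the hematoxylin/eosin/residual
   unit vectors form a 3×3 basis `S`; per-stain concentrations are `S⁻¹ · OD`
   per pixel.
3. **Nuclear segmentation.** The hematoxylin channel is thresholded at the
   256-bin cut minimizing intra-class variance (Otsu). Each blob is refined
   by (i) an EM fit of up to three Gaussians to its intensity distribution
   (BIC-selected; well-separated components split merged nuclei with
   different chromatin content) and (ii) a convexity test — blobs with
   solidity below threshold are cut along chords joining boundary concavity
   points, recursively.
4. **Morphometry.** Per nucleus: centroid, area, perimeter, eccentricity,
   solidity, hematoxylin mean/SD, and a **cellularity index** — the inverse
   of the nucleus's Voronoi region area (regions clipped to the tile).
5. **Equal-weight normalization.** Per feature: pool all tissues' values,
   re-bin the pooled distribution into B equal-population bins, and remap
   each tissue onto those global bins, giving a length-B probability vector
   per tissue; multiple sections per patient are averaged.
6. **Consensus subtyping.** Patients (concatenated area + cellularity
   distributions) are repeatedly subsampled and k-means clustered; the
   consensus matrix of co-clustering frequencies is scanned over candidate
   K, selecting the K with the fewest ambiguous entries (PAC score).
7. **Survival.** Within each subtype, Kaplan–Meier curves
   `S(t) = Π (1 − dᵢ/nᵢ)` and a pair-wise log-rank test compare
   more-intensive vs less-intensive treatment groups.

Large images are partitioned into 1k-by-1k blocks processed independently
with a margin of context; a nucleus belongs to the block containing its
centroid, so block decomposition never double-counts.

## Worked example

```python
from hemorph import (SegmentationConfig, TileSimParams, generate_he_tile,
                     generate_reference_tile, segment_tile)
from hemorph.morphometry import extract_features, records_to_frame
from hemorph.segmentation import hematoxylin_channel

reference = generate_reference_tile()
tile, truth = generate_he_tile(TileSimParams(seed=0))   # 512x512, 100 nuclei
mask = segment_tile(tile, reference)
hema = hematoxylin_channel(tile, reference)
frame = records_to_frame(extract_features(mask, hema, "demo"))
print(mask.n_labels)
print(frame[["area", "mean_h", "cellularity"]].describe().loc[["mean", "std"]])
```

prints

```
102
            area    mean_h  cellularity
mean  219.872549  0.771144     0.000464
std   114.537786  0.104408     0.000214
```

— 102 detections for 100 planted nuclei (matched recall and precision on
this tile are 1.00 and 0.98 at 5 px centroid tolerance; see
`scripts/acceptance.py`). Mean detected area ≈ 220 px² matches the planted
lognormal radius distribution (median radius 8 px ⇒ median area ≈ 201 px²),
mean hematoxylin concentration ≈ 0.77 OD sits near the generator's
per-nucleus mean of 0.7, and mean cellularity ≈ 4.6×10⁻⁴ px⁻² is consistent
with ~100 Voronoi cells tiling 512² px (100/512² ≈ 3.8×10⁻⁴, boundary cells
clipped smaller).

The same stages are available from the shell:

```bash
hemorph simulate reference --out ref.tif
hemorph simulate tile --nuclei 100 --seed 0 --out tiledir
hemorph segment --in tiledir/tile.tif --ref ref.tif --out segdir
hemorph features --in tiledir/tile.tif --ref ref.tif --mask segdir/mask.tif --out features.csv
hemorph run --config config.json          # end-to-end over a cohort
```

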