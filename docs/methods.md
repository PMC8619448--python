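# Methods

## Problem setting and model

The package targets parcels where planting is a uniform lattice: trunks a
fixed distance `d_intra` apart within rows a fixed distance `d_inter` apart,
and crown diameters bounded by `D_max`. When `D_max > d_intra` neighboring
crowns merge (semi-overlap) and per-tree crown polygons are ill-defined; the
package therefore never attempts them. Instead it treats each tree's canopy
as *the canopy observed inside a square box of side `D_max` centered on the
planted position*, and classifies trees by that quantity. The defaults —
`d_intra` = 2 m, `d_inter` = 6 m, `D_max` = 3 m, 0.5 m/pixel — describe a
commercial citrus layout; at that resolution the spacings are exactly 4 and
12 pixels and the box side is 6 pixels, giving a 2-pixel (1 m) shared strip
between in-row neighbors.

Assumptions, made explicit:

- the raster is already clipped to the parcel, with nodata outside it;
- bands share one radiometric scale (values are treated as unitless
  intensities — DN vs reflectance does not matter to k-means on raw
  vectors; a `standardize` switch enables per-band z-scoring otherwise);
- rows are straight and the lattice uniform; curved rows are out of scope;
- anchors are supplied by a human (semi-automatic workflow by design).

## Stage-by-stage choices

**Segmentation.** k-means over all non-nodata pixel spectra,
k-means++ initialization, 10 restarts, relative tolerance 1e-4, max 300
iterations, seeded. The returned labeling is the nearest-centroid assignment
under the converged centroids, so one further Lloyd step changes nothing.
Semantics are assigned *after* clustering: the canopy cluster is the one
with the highest mean NDVI (ε = 1e-9 guards the ratio), or highest mean
green without NIR; ties break to the lower cluster id. Background is taken
from the nodata mask when the raster carries one; otherwise it emerges as
its own (dark) cluster. Degenerate inputs with fewer distinct spectra than k
(a noise-free two-material parcel) clamp k down with a warning rather than
fail, since the extra clusters could only be empty or duplicated. The Otsu
baseline thresholds a single grayscale (NDVI when available, else the band
mean); whichever side has the higher vegetation score becomes canopy; a
constant image yields an all-zero mask with a warning.

**Localization.** Directions of the lattice basis come from the anchor
geometry but magnitudes from the declared distances, because clicked anchors
carry pixel-level error while the distances are surveyed. Anchors may be
fractional pixels; with integer anchors a worst-case half-pixel error on a
4-pixel baseline tilts the row direction by up to ~7°, which compounds over
a 25-tree row — subpixel anchors avoid this entirely. Lattice indices are
iterated over the (slightly expanded) raster bounding box rather than
looping over pixels — identical output, far cheaper. Candidates round
half-up per axis to a pixel; a candidate is kept iff that pixel is in-bounds
and non-nodata, which confines the grid to the parcel and makes row ends
implicit. Indices renumber from the minimal kept lattice index so
(row, tree) start at (0, 0). Missing trees at row ends are indistinguishable
from a short row; no disambiguation is attempted.

**Boxes and counting.** Box side `s = round(D_max/GSD)`; an even side cannot
center on a pixel, so the window anchors at `center − ⌊s/2⌋` (bias ≤ half a
pixel). Windows clip at raster edges. Counts are plain sums of mask-1 pixels
per window; overlapping pixels count for every box covering them — the
double counting is intentional and mirrors how a field agronomist would
attribute shared canopy to both neighbors.

**Classification.** Thresholds `t1 = min + avg/5`, `t2 = max − avg/5` are
always derived from the per-parcel min/mean/max of the box counts (never
pooled across parcels, never stored independently). All boxes enter the
average, including near-zero (missing-tree) boxes. Rules are evaluated in
order 1, 2, 3 with the first match winning; this makes the classifier
monotone in the count and resolves the degenerate case `t1 > t2` (possible
when `max − min < 2·avg/5`), which is warned about but not an error. Counts
are in pixels; m² is a derived convenience column (`count × GSD²`).

**Mapping.** The class map starts all-zero and each box paints its class
value over its window; overlap pixels take the class of the nearest box
center with ties to the lower tree id. The rule is order-independent, so the
rendering is byte-reproducible under box permutation. Colors: red =
missing/weak, blue = normal, yellow = big (documented constants; the palette
is written into the GeoTIFF color table).

**Scoring.** Pixel precision `TP/(TP+FP)` and `F1 = TP/(TP + (FP+FN)/2)`
over non-nodata pixels; recall is emitted as a bonus column. Sample-based
scoring pools TP/FP/FN over samples (micro-average). Undefined denominators
(empty prediction, or empty prediction *and* truth) are flagged as NaN, not
zeroed.

## Synthetic scenes

The generator emulates the study geometry: a rotatable row lattice at the
configured spacings, crowns as ideal filled disks with a per-tree diameter
drawn from a configurable law (uniform 1.8–3.0 m by default, point mass
`p_missing` = 0.1 at zero), vegetation/soil/background spectra, and i.i.d.
additive Gaussian band noise. Default spectra give NDVI ≈ 0.71 over canopy
and ≈ 0.10 over soil — a plausible citrus/soil contrast; the values are
configuration, not claims. The parcel is the lattice bounding rectangle
padded by one crown radius; outside it the scene is either flagged nodata
(default, matching a clipped GeoTIFF) or filled with a dark background
spectrum (`background="fill"`), in which case the image holds three pixel
strata and no nodata. Default noise SD is 0.01 (≈ 8.7 SDs of
vegetation/soil contrast), i.e. mild sensor noise.

Spectral contrast is summarized as
`separation = ‖μ_veg − μ_soil‖ / (√n_bands · σ_noise)` — the RMS per-band
mean difference in units of the per-band noise SD. The stressed operating
point used in the tests sets σ so this separation equals 3.

Truth classes are computed by running the package's own
thresholds/classifier on the true per-box counts of the true disk-union
mask; tests verify those counts against an independent per-pixel recount.

What the generator does **not** model: crown texture and within-crown
spectral variability, shadows, atmospheric and view-angle effects, spatial
noise correlation, registration error between image and planting survey,
and irregular parcel boundaries. Passing tests therefore establish the
correctness of the geometry, counting, classification and scoring machinery
and the behavior of k-means under isotropic spectral noise — not
segmentation accuracy on real imagery, which depends on the real
disturbances above and on label quality.

## Numerical conventions

- Pixel coordinates are (row, col), 0-based; geographic lookups use pixel
  centers; metric lengths convert to pixels by round-half-up.
- Affine geotransforms use GDAL coefficient order; north-up rasters are
  written with pixel-scale + tiepoint tags, rotated ones with the full
  model-transformation matrix.
- One seed feeds both k-means and scene generation; the acceptance script
  derives stage seeds by fixed small offsets.
- Problem sizes in the test and acceptance suites: the reference scene is
  10 rows × 25 trees (≈ 119 × 107 px), stage tests use 4 × 8 scenes, and
  brute-force oracle comparisons run on 20 random scenes of 2–4 rows ×
  3–7 trees; these sizes already exercise every code path (rotation,
  clipping, overlap, missing trees) while keeping the whole suite in a few
  seconds.

## Known limitations

- The weak-vs-missing confound is inherent to box sampling: an empty
  position's box collects canopy from neighbors that branch into the gap,
  so class 1 undercounts true missing trees.
- Classes are relative to the parcel (thresholds derive from that parcel's
  own min/mean/max), so class labels are not comparable across parcels with
  different vigor.
- Even box sides bias windows by up to half a pixel toward the top-left.
- No reprojection: raster and anchors must share one CRS and grid.
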