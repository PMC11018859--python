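# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of the `hifi` package: a toolkit for hyperplexed (cyclic)
immunofluorescence whole-slide imaging — multi-round image alignment with
autofluorescence removal, single-cell measurement, SOM-based phenotyping,
and spatial-organization statistics.

## Image model and coordinate conventions

Images are 2D grids of non-negative 16-bit intensities with an isotropic
pixel size in µm. The pixel-index origin is top-left, axes are (row, col),
and physical coordinates are `index * pixel_size` with pixel-center
semantics. Anisotropic pixels are rejected at read time; slide scanners in
this workflow produce isotropic pixels. On disk, stacks are tiled OME-TIFFs
with one channel per IFD, channel names in the OME XML, and dyadic pyramid
levels (level k has shape `ceil(shape / 2^k)`); level 0 is always lossless
(zlib by default, configurable, lossless only). Vendor formats (CZI) are
out of scope — convert with `bioformats2raw`/`bfconvert` or export OME-TIFF
from the acquisition software.

Because each channel occupies its own chunked IFD, `stream_channel` decodes
one channel with a peak working set of one full-resolution channel plus
constant overhead, never the whole stack. This is the property that lets
45-plus-channel whole-slide experiments run on ordinary workstations.

## Registration

Cyclic staining requires re-mounting the slide every round, so rounds are
related by small rigid (occasionally affine) motions. Round 1's DAPI channel
is the fixed reference for *every* other round — chaining round k to round
k−1 would accumulate drift. The transform maps moving coordinates into
reference coordinates, `x_ref = A x_mov + t` (2×3 matrix, (row, col)
convention); rigid transforms keep `det(A) = +1` within 1e-6.

`estimate_transform` minimises the squared intensity difference between the
reference and the warped moving DAPI over a Gaussian coarse-to-fine pyramid
of depth `ceil(log2(min_dim / 64))`. The coarsest level is initialised by
upsampled phase correlation (translation only); each level then refines the
parameters (rotation + translation, or a full 6-parameter affine
perturbation) with trust-region least squares on the masked residual image.
Convergence is a parameter update below 1e-4 pixel-equivalents or 100
function evaluations per level. Two numerical details matter:

* The residual mask is the warped footprint at the incoming parameters
  intersected with an interior margin (1/32 of the image side), held fixed
  during each level's refinement. This removes the bias from
  constant-filled out-of-frame pixels without re-warping a mask per
  evaluation.
* Pyramid levels whose smaller dimension exceeds `refine_max_dim`
  (default 1024) carry the coarser solution upward (translations doubled)
  without another optimisation pass. By that point the solution has
  converged far below resampling accuracy — measured landmark RMS error on
  2048² synthetic pairs is ~0.02 px against a 0.5 px contract — and a
  full-resolution pass would dominate runtime for no measurable gain. Set
  `refine_max_dim` to the image size to force refinement everywhere.

Warping uses bilinear interpolation (`apply_transform`), required for
sub-pixel motion, and clamps at zero. Channels are warped strictly one at a
time, preserving the memory contract through `align_experiment`.

## Background and autofluorescence removal

Rolling-ball background subtraction uses a 75 µm ball diameter, converted
to pixels through the pixel size. For large balls the background is
estimated on a block-shrunk copy (shrink factor `radius_px // 16`) and
linearly interpolated back — the standard acceleration for this filter —
then clipped from above by the image so the estimate can never exceed the
data. By default it runs on raw tiles before alignment (it is a
tile-post-processing step), but the order is configurable.

Unstained tissue is imaged before antibody labeling; this autofluorescence
(AF) round is treated as "round 0", registered to the round-1 reference like
any other round, and subtracted pixel-by-pixel from each aligned marker
channel: `out = max(channel − scale·af, 0)`, with `af` the AF channel
matched by excitation/emission. Channels carrying endogenous signal in an
AF-overlapping band (e.g. GFP in reporter lines) are listed in
`skip_af_channels` and are warped but never subtracted. All subtraction
output is clamped at zero (16-bit unsigned output domain). By default only
the round-1 DAPI is kept in the assembled stack (`keep_dapi="first"`).

## Region masks and derived niches

Base regions (lesion, tumor, brain, vessel, ECM, excluded artifacts) come
either from imports (label TIFF or QuPath-style GeoJSON) or from a small
baseline pixel classifier: logistic regression on per-channel raw intensity
plus Gaussian-smoothed features at σ = 2 and 8 px, trained on positive and
negative scribbles, seeded and deterministic. This baseline fills the role
of a full digital-pathology ANN classifier without reproducing one;
externally trained masks are the expected production path. The excluded
mask is always imported (artifact QC is manual) and is subtracted from all
downstream analyses.

Mask clean-up removes foreground fragments below a per-region pixel
threshold and then fills enclosed holes below the hole threshold —
fragments first, holes second, the one order that makes the operation
idempotent. The per-region constants are in pixels as used in the source
workflow: lesion 20,000; vessel 20; tumor/brain 4,000; ECM holes 50 /
fragments 300.

Derived niches are reproducible functions of the base masks:

* lesion context — lesion dilated 750 µm into the parenchyma;
* perivascular — vessels dilated 15 µm, vessel core removed;
* tumor border — the tumor–brain interface dilated 70 µm. The interface is
  defined as tumor pixels 8-adjacent to brain (a 1-px line for touching
  masks): classifier-produced tumor/brain masks abut rather than overlap,
  and the one-sided definition keeps the zero-width border a single-pixel
  line and the 70 µm band at the expected ~141 px total width.

Dilations use exact Euclidean distance transforms (`EDT <= radius`), not
iterated structuring elements.

## Single-cell objects

External nuclear detections arrive as label maps with per-object
probabilities (any segmenter that emits them); a threshold-based watershed
baseline (Otsu → EDT maxima seeds → watershed) is built in for data without
an external model. Overlapping detections (e.g. from polygon annotations)
are resolved by per-object interior distance maps: a contested pixel
belongs to the object whose own EDT is strictly greatest there, ties go to
background. A consequence worth knowing: an object fully nested inside
another can never strictly win (its background is a superset, so its EDT is
pointwise ≤) and is eliminated entirely.

Detections with probability < 0.5 are dropped, as are nuclei below
`min_nucleus_area_um2` (default 4 µm², configurable — fragment removal has
no canonical threshold). Each nucleus is expanded by 2.5 µm toward the
nearest-nucleus frontier (cells stay disjoint by construction), capped so
that `area(cell) ≤ 1.5 × area(nucleus)` by dropping the farthest candidate
pixels first (ties broken in raster order). Sub-pixel radii are converted
to pixels through the EDT, so no rounding of the radius itself is needed.

Four measurement zones per object: nucleus, cytoplasm (cell minus nucleus),
whole cell, and membrane. The membrane is the 1-px inner boundary ring of
the cell mask (width configurable) — the minimal reading of a "membrane"
zone for pixel-grid objects. Measurements per cell: centroid (µm),
area/perimeter/circularity of nucleus and cell (circularity
`4πA/P²`, clipped at 1.0 against discretization overshoot), mean
fluorescence intensity (MFI) per marker per zone (empty zones yield missing
values, not zeros), distance from the nucleus centroid to the nearest
boundary pixel of each region mask (KD-tree over boundary pixels), and
region membership flags. Cells whose centroid falls in the excluded mask
are dropped. Tables export as CSV/Parquet with the stable schema
`mfi__<marker>__<zone>`, `dist__<region>`, `in__<region>`.

## Phenotyping

Classification features are per-marker MFIs, nuclear or whole-cell
according to each marker's biology (`MarkerConfig`). Each feature is
clipped at its 99.7th-percentile value (linear-interpolation quantile —
the convention matters at small n and is fixed here) and min-max scaled to
[0, 1]; constant markers scale to 0 with a warning; the scaling parameters
are returned for reuse.

Clustering uses a 10×10 self-organizing map (100 nodes), implemented as a
classic online Kohonen map: codebook initialised by sampling data points,
Gaussian neighborhood with σ decaying linearly 5 → 0.5 over 10 epochs,
learning rate 0.5 → 0.01, rectangular grid, fully seeded. Grid size is the
method's convention; the other hyperparameters are unexceptional SOM
defaults, all exposed. Cells map to their best-matching unit (Euclidean,
ties to the lowest node id). Node codebooks are metaclustered by
agglomerative clustering (average linkage, Euclidean) cut at k — plain
hierarchical clustering of codebooks rather than an MST-based heuristic,
since metaclustering here only guides a manual annotation. The annotation
(node → metacluster → cell-type label) is user-supplied YAML, as phenotype
naming is a biological judgement; an unannotated node is an error naming
the node.

Batches are scaled, trained, and clustered independently (avoiding batch
effects) and merged at the point of annotation under a shared label
vocabulary. Models persist as portable JSON (codebook + scaling + seed).

## Spatial statistics

All analytics consume tidy cell tables (`image_id`, `group`, `x_um`,
`y_um`, `cell_type`, optional `in__<region>` flags).

**Composition** — counts and percents per image × region × cell type;
percents per (image, region) sum to 100.

**Shannon diversity** — `H' = −Σ p_i ln p_i` per image over cell-type
proportions (natural log, p > 0 terms; log base configurable), with the
group mean µH′ reported. Natural log matches the magnitude of published
values over ~20 types.

**Nearest-neighbor distances** — for every ordered type pair (A, B) and
image, the mean over A cells of the distance to the nearest B cell (same
type uses the nearest *other* cell); pairs with a type absent are missing,
not zero. KD-tree queries are tested for exact agreement with O(n²) brute
force. Group matrices hold the mean and SD of per-image means (SD with
ddof = 1).

**Proximity networks** — directed means are symmetrized per unordered pair
(arithmetic mean of the two directed means; SD pooled as the root mean
square), since an undirected graph needs one value per pair while the
directed values remain available. Edge width is `100 / SD` (the constant is
aesthetic); edges whose width falls below `median(SD) × 0.8` are removed —
the rule is applied literally as stated, width against an SD-scale
threshold, which on µm-scale SDs prunes the high-variability edges. Node
sizes bin percent-total monotonically: ≤ 1% → 3, ≥ 25% → 70, eight linear
bins between (only the endpoints are canonical). Node communities come from
Louvain at resolution 1.5 with a fixed seed; the force-directed layout with
target lengths proportional to mean distance is cosmetic and only tested
for being seeded.

**Cellular neighborhoods (CNs)** — each cell's neighborhood is the
composition vector of cell types within a 30 µm radius (self excluded;
fractions sum to 1; isolated cells flagged). Profiles pool across images
and k-means (seeded, k = 15 by default) yields CN ids; centers are fitted
on cells with at least one neighbor (so CN mean-composition rows sum to 1)
and isolated cells are assigned to the nearest center. Per-CN mean
composition (the heatmap input) and per-image CN percents are returned.

**Interaction test** — the classical permutation test: per image and
ordered pair (A, B), the statistic is the mean number of B neighbors per A
cell on the fixed 30 µm connectivity graph; the null permutes cell-type
labels within the image (type counts preserved) 1000 times;
`p_gt = (1 + #{perm ≥ obs}) / (n_perm + 1)` tests attraction, `p_lt`
avoidance; `sigval ∈ {−1, 0, +1}` at α = 0.01. Per-image RNG streams derive
from the master seed, so results are independent of execution order. The
radius is 30 µm (the connectivity-map convention; a diameter reading, i.e.
15 µm radius, is available via the `radius_um` flag). Two aggregate
summaries are exported per group and pair — the signed sum of per-image
significance indicators (`sum_sigval`, attraction positive) and the mean
sum of the two one-tailed p values — because both conventions circulate;
the signed sum is the headline column.

## Synthetic data

The generators define the fixture conditions under which every contract is
tested; everything is deterministic under a master seed with stably derived
sub-streams, and ground truth is always emitted.

* `make_cyclic_rounds` — blob nuclei (Gaussian profiles, radii 6–11 px,
  ~400 per 1024² field) plus a smooth band-limited autofluorescence field
  shared across channels; rounds k ≥ 2 and the AF round are resampled from
  the reference scene by the inverse true transform with the same bilinear
  interpolator the alignment uses, so registration error is measurable
  without interpolation confounds. Default perturbations span the realistic
  re-mounting range (|shift| ≤ 25 px, |rotation| ≤ 2°). Noise is
  Poisson-distributed photon noise (gain 30) plus small Gaussian read
  noise — the right family for fluorescence statistics.
* `make_nuclei_image` — packed wobbly-boundary nuclei with radial +
  angular intensity modulation (emulating non-uniform chromatin staining),
  with center spacing shrinking as density grows: low density guarantees
  disjoint objects, high density produces touching pairs that stress the
  watershed and overlap-resolution code.
* `make_marker_table` — Gaussian phenotype mixtures with configurable
  centroids, within-class SD, and weights; MFIs clamped at 0.
* `make_point_pattern` — CSR (uniform), Neyman–Scott parent–offspring
  clusters (shared parents plant attraction, separate parents plant
  segregation), and segregated strips with a controllable gap (planting
  avoidance and spatial niches).

What the fixtures do **not** emulate: real tissue texture and optical PSFs,
stain spillover between spectrally adjacent channels, segmentation errors
of a real CNN detector, deformable (non-planar) tissue motion, and
intensity batch drift. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under the stated models, not
robustness to every artifact of real slides.

## Problem sizes and numerical tolerances in the test suite

End-to-end checks run at sizes chosen to exercise whole-slide code paths on
one CPU: 20 registration pairs at 2048² (landmark RMS < 0.5 px contract;
measured ~0.02–0.23 px), 500-cell expansion fields, 10,000-cell phenotype
mixtures with centroid separation ≥ 5× the within-class SD (ARI ≥ 0.9
contract; measured ≥ 0.99), 2,000-cell brute-force distance comparisons
(exact agreement), and 200 simulated images for type-I calibration of the
interaction test at α = 0.01 with 1000 permutations (rejection rate within
the 95% binomial interval; the add-one p-value estimator makes the test
conservative under heavy ties). `scripts/acceptance.py` recomputes the same
quantities at slightly reduced sizes (10 registration pairs at 1024²,
300-cell zoning fields) and writes them as JSON.

## Known limitations

* Registration covers rigid and affine motion only; no deformable model.
* The GeoJSON mask exporter traces exterior contours only (holes are not
  preserved); TIFF round-trips are exact.
* The baseline watershed segmenter is a fallback; production use expects
  an external deep-learning detector's label maps and probabilities.
* The online SOM is O(n · epochs · nodes) in Python/NumPy — ample for
  10⁵–10⁶ cells, not tuned beyond that.
* Tile stitching and flat-field correction are upstream (vendor) steps and
  out of scope.
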