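# Methods

This note documents the models, algorithms and numerical choices behind
`phenoprofiler`, the assumptions they rest on, and what the synthetic
benchmarks do and do not establish about real microscopy data.

## Scope and data model

The pipeline operates on 2D multichannel intensity planes (16-bit range);
z-stacks are collapsed by maximum-intensity projection at read time, so all
geometry is planar.  Coordinates are 0-based `(row, col) = (y, x)` and all
measurements are in pixels, converted to micrometres only at reporting time
when a pixel size is supplied.  Channel roles (nucleus, golgi, tubulin,
cilia, actin, centriole, edu, ki67, aurka) are bound to channel names by an
explicit JSON map, never inferred from file metadata — format conversions
routinely scramble metadata, and a wrong silent guess is worse than a
required config line.  Values are taken verbatim even when 12-bit data
occupy 16-bit containers; thresholding and robust scaling are invariant to
such global gain anyway.

## Segmentation

Cell boundaries are expected from an external segmenter via an integer
label mask.  The built-in fallback thresholds the nucleus channel (Otsu),
takes 8-connected components ≥ 50 px as seeds, and grows cells by watershed
on the smoothed inverted cytoplasmic marker (tubulin or actin) restricted
to that marker's Otsu foreground; without a cytoplasmic role, seeds are
dilated by a fixed radius.  A signal guard treats the nucleus channel as
empty when the Otsu split covers more than half the frame or separates
class means by less than 3 background standard deviations — the behaviour
of Otsu on unimodal noise is to split the noise itself, which would
otherwise fabricate "cells" in empty images.

Subcellular structures are binarized with whole-image Otsu/Yen thresholds
and intersected with each cell: per-cell thresholds destabilize for cells
whose structure is absent (the threshold then lands inside noise).  A
per-cell switch exists for users whose illumination varies strongly across
the field.  Structure masks are despeckled (8-connected components < 5 px
removed): isolated above-threshold noise pixels are not structures, and
without this step a two-pixel speck in an otherwise Golgi-free cell
produces degenerate area/CV/distance features whose robust z-scores reach
the hundreds and dominate every Euclidean distance downstream.

Thresholds use one histogram bin per integer level for integer planes
(256 bins otherwise); connected components use 8-connectivity throughout,
because thin fluorescent structures continue diagonally.  Cells under
200 px are dropped as shards; border-touching cells are excluded from
feature analysis by default since truncated morphology biases area and
shape features.

## Puncta detection

Peaks are detected in the Crocker–Grier style: bandpass
`max(0, G_σ∗I − B_L∗I)` with σ = 1 and boxcar side L = diameter
(reflective boundaries), strict local maxima within a
separation × separation window above the 64th percentile of *positive*
bandpassed pixels (background zeros would collapse the percentile),
subpixel centers by intensity-weighted centroid over the radius-⌊d/2⌋
disk, an integrated-mass cutoff, and greedy suppression of peaks closer
than the separation (larger mass wins).  Determinism on quantized images
is guaranteed by breaking plateau ties toward the topmost-then-leftmost
pixel.  Bandpass output below 10⁻⁹ of its maximum is floored to zero:
far Gaussian tails leave positive numerical dust that would otherwise
enter the percentile and spawn fake maxima on noiseless test images.

Default mass cutoffs (Golgi 1000, tubulin 3000, in bandpassed-intensity
units) sit between the mass scale of background maxima and the dimmest
genuine structure of each channel; both are per-channel configuration, as
any real experiment will need to place them against its own staining
intensities.  Spindle-pole counting runs the detector on the tubulin
channel restricted to the cell's bounding box with the cell mask applied.

`peaks_xy_std = sqrt(var(y) + var(x))` uses population variances — it is
the RMS distance of peaks from their centroid — and is 0 for ≤ 1 peak.

## Skeleton morphometry

Thinning uses the classic two-subiteration (Zhang–Suen) algorithm.  Object
length is the total weight of a minimum spanning traversal of the
component's 8-adjacency graph with axial steps 1 and diagonal steps √2;
this gives 99 for a 100-px straight line and 49√2 for a 50-px diagonal, and
stays within 2% of Euclidean length at 0°/45°/90°.  Endpoints are skeleton
pixels with exactly one neighbor.  A cilium call requires an object of
1–15 µm (pixel-converted; typical primary-cilium lengths) with exactly two
endpoints — branched blobs are rejected.  The per-image ciliated fraction
divides whole-image cilium count by whole-image nucleus count, independent
of cell segmentation, so unsegmentable cells still contribute.

## Shape features

Circularity is `4πA/P²` with the perimeter measured as the length of the
marching-squares sub-pixel contour simplified by Douglas–Peucker at 1.5 px
tolerance.  Raw chain-code step counting (1/√2 weights) overestimates
smooth digital contours by ~4–5%, which would cap a disk's circularity near
0.91; Crofton-type estimators are nearly exact on disks but overshoot
squares by ~12%.  Simplifying the contour polygon at the quantization scale
removes the staircase bias (digital disk r = 50 → 0.996; 100×100 square →
0.793 ≈ π/4; 1×100 bar → 0.03) while remaining robust to the coarser
staircase of 2× nearest-neighbor upsampling.  The cost is that rotation by
90° is invariant only to ~0.01 (the simplification restarts at a different
contour vertex), and circularity may slightly exceed 1 on small disks — it
is capped at 1.2, not 1.0, to keep discretization visible.  Nuclear aspect
ratio is the axis ratio of the second-moment-equivalent ellipse, capped at
100 for degenerate (zero-minor-axis) masks.

Centers of mass are intensity-weighted within the binarized structure
masks (a flat signal falls back to the binary centroid).  Nuclear marker
means (EdU, Ki-67) subtract the median intensity of the image outside all
nuclei dilated by 5 px, and may legitimately be negative.  Centrosomal
marker accumulation is the marker mean over a disk (default r = 5 px) at
the brightest centriole-channel punctum minus the median over the r..2r
annulus, clipped at zero.

Missing structures yield explicit missing values, never zeros — a zero
Golgi area is a phenotype; an unmeasurable one is not.

## Profiling

Tables from multiple images are concatenated; feature columns missing in
more than half the cells are dropped, the rest median-imputed with an
`<col>_imputed` flag column per affected feature.  Robust z-scores use
`(x − median)/(Q3 − Q1)` with linearly interpolated quartiles; zero-IQR
columns are dropped with a warning.  Crucially, the scaling statistics are
fitted on *observed* values only: imputed entries all equal the column
median, and letting them into the quartiles collapses the IQR of any
column with ≳ 50% missingness, exploding the z-scores of the observed
values.  Scaling is fitted on the combined table across conditions so that
z-scores are comparable between conditions.

Density clustering implements DBSCAN semantics deterministically: a core
point has ≥ `min_samples` neighbors (itself included) within inclusive
Euclidean radius eps; clusters are connected components of core points;
border points join the cluster of their lowest-index core neighbor; labels
are relabeled contiguously by descending cluster size with noise at −1.
Radius queries go through a KD-tree; the cluster logic itself is authored
here so the tie rule is explicit, and the test suite checks exact partition
agreement against both an O(N²) reference and scikit-learn's DBSCAN (on
core points, where all correct implementations must agree).  When eps is
not given it is chosen by the k-distance elbow (k = min_samples): the point
of maximum deviation below the chord of the sorted k-th-neighbor-distance
curve, which is convex (flat bulk, sharp tail).  The chosen eps is logged
and written to the run record.  Clustering operates on the scaled feature
table by default; clustering on a 2D embedding instead is supported, since
which space the field's workflows cluster in varies.

The 2D embedding backend is pluggable: exact PCA (deterministic, with a
sign convention fixing the largest-magnitude loading positive) is built in,
UMAP is used when importable.  All tests use the deterministic PCA backend.

Median splits label cells 1 (≤ threshold) or 2 (>), with the threshold
taken as the reference subset's median — ties go to subcluster 1.

## Synthetic scenes

The generator renders what the pipeline claims to measure, with full
ground truth: elliptical cells (interphase semi-axis ~40 px, elongation
1.15–1.7; mitotic ~18 px, nearly round — echoing mitotic rounding),
nuclei at 45% of the cell radius (mitotic: a condensed plate), Golgi as
packed (3–8 puncta in a 30° sector at 25 px from the nucleus centroid),
dispersed (12–30 puncta uniform in the cytoplasm), fragmented (short
segments), hazy (broad dim blob, also forced for mitotic cells so they
carry no skeletonizable Golgi) or absent; interphase microtubule networks
vs 1/2/3/4 bright spindle poles on a ring at 0.55 r; one anti-aliased
3–8 µm cilium per ciliated interphase cell, laid over the cell body; 1–2
centriole foci on the perinuclear axis shared with the packed-Golgi
sector; EdU/Ki-67 nuclear fills (Ki-67 with nucleolar foci to give CV
texture) and a centrosomal marker blob with per-cell amplitude.  Poisson
shot noise is applied to signal + background (default 100 counts),
then Gaussian read noise (σ = 5), giving punctum SNR well above 5.
Pixel size defaults to 0.2877 µm (a typical 40× confocal sampling).

All sampling draws from one seeded generator in a fixed per-cell order, so
a seed fixes the scene bit-exactly and the truth record can never
desynchronize from the image.  Cell placement is rejection sampling with
non-overlap margins; an over-packed frame raises an error rather than
silently overlapping cells.

The mitotic fraction defaults to 0.25 and the interphase Golgi-state prior
to packed/dispersed/fragmented/hazy/none = 0.40/0.30/0.15/0.10/0.05 —
a population in which Golgi-state subgroups are genuine phenotypic
subpopulations.  For the two-phenotype separation benchmark
(`two_population_spec`), interphase cells all carry packed Golgi so that
generator truth defines exactly two phenotypes; with the full prior, a
density clusterer correctly resolves the Golgi states as additional
clusters and an interphase/mitotic Rand index is not the right score.

### What the benchmarks do and do not show

The generator's cells are smooth ellipses with ideal PSF-like puncta, no
illumination gradients, no spectral bleed-through, no overlapping or
touching cells, and noise that is exactly Poisson + Gaussian.  Passing
benchmarks therefore establishes the *algorithmic* correctness of each
stage (detection, measurement, scaling, clustering) and end-to-end
recoverability of known effects at realistic SNR — not robustness to
autofluorescence, debris, segmentation errors or staining variability.
Threshold-class defaults (peak mass cutoffs, cilium length window,
centrosome disk radius) are expected to need per-experiment adjustment on
real data and are all exposed in configuration.

## Benchmark problem sizes

The shipped acceptance computation uses 100 random 64×64 images for the
peak-detector oracle, 100 mitotic cells per pole count k ∈ {1, 2, 4},
200 packed + 200 dispersed cells for Golgi-state separation and distance
recovery, 300 mixed cells for phenotype separation, 500 cells at 40%
ciliation for fraction recovery, 5 amplitude points × 50 cells for marker
linearity, and 50 seeded instances (N ≤ 300) for the density-clustering
oracle — sizes at which the binomial/rank statistics involved are already
stable while the whole computation stays desk-scale.
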