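# phenoprofiler

Image-based single-cell phenotype profiling of organelle morphology from
multichannel fluorescence microscopy.

High-content imaging experiments routinely stain cells for DNA (DAPI),
microtubules (α-tubulin), the Golgi apparatus (GM130/GRASP65), actin,
primary cilia (acetylated tubulin), centrioles (centrin/γ-tubulin) and
cell-cycle markers (EdU, Ki-67), and need every cell in every image reduced
to a vector of *interpretable* morphological numbers — not a black-box
embedding.  `phenoprofiler` does exactly that: given a 16-bit multichannel
TIFF and a per-cell label mask (from cellpose or any other segmenter; a
watershed fallback is built in), it measures a catalog of named features per
cell, combines cells from many images into one table, standardizes it, and
resolves phenotypic subpopulations by density clustering.

## The measurements

* **Puncta statistics** — organelles abstracted as discrete fluorescence
  peaks, detected Crocker–Grier style: bandpass `max(0, G_σ∗I − B_L∗I)`,
  strict local maxima within a separation neighborhood, subpixel refinement
  by intensity-weighted centroid, and an integrated-mass filter.  A compact
  Golgi gives few peaks with small coordinate spread
  `peaks_xy_std = sqrt(var(y) + var(x))`; a dispersed or fragmented Golgi
  gives many spread-out peaks; the number of α-tubulin peaks in a mitotic
  cell counts spindle poles (monopolar / bipolar / multipolar).
* **Skeleton morphometry** — structures thinned to 1-px lines; object count
  and traversal length (axial step 1, diagonal √2) quantify Golgi
  fragmentation, and a short unbranched skeleton line in the
  acetylated-tubulin channel (1–15 µm, exactly two endpoints) is a primary
  cilium.  The per-image ciliated fraction is cilia / nuclei.
* **Shape and intensity** — cell mask area and circularity `4πA/P²`,
  moment-ellipse nuclear aspect ratio, per-structure area / mean / CV,
  intensity-weighted center-of-mass distances (nucleus–Golgi,
  nucleus–centrosome, Golgi–centrosome), background-subtracted nuclear
  marker means (EdU, Ki-67), and marker accumulation at the centrosome
  (disk minus annulus around the brightest centriole focus).
* **Profiling** — tables are combined, median-imputed with audit flags,
  standardized by robust z-scores `(x − median)/IQR`, optionally embedded
  (PCA built in, UMAP if installed), and clustered with a deterministic
  DBSCAN (noise = −1, border points join the lowest-index core neighbor).
  Subpopulations can be split at a reference group's feature median.

A fully ground-truthed synthetic scene generator (`phenoprofiler.synthetic`)
renders cell populations with known Golgi states (packed / dispersed /
fragmented / hazy), spindle pole counts, cilia and marker amplitudes under
Poisson + Gaussian noise, so every stage is testable without microscope
data.

## Worked example

```python
import pandas as pd
from phenoprofiler import (
    SceneSpec, render_scene, default_channel_map, profile_image,
    assemble, robust_scale, dbscan,
)

spec = SceneSpec(n_cells=20, shape=(700, 700), seed=42, ciliated_prob=0.3)
image, labels, truth = render_scene(spec)

table = profile_image(image, labels, default_channel_map(), condition="control")
print(table[["cell_id", "mask_area", "circularity", "peaks_num_Golgi",
             "peaks_xy_std_Golgi", "dist_nuc_Golgi", "objects_num_cilia"]]
      .head(5).round(2).to_string(index=False))

scaled = robust_scale(assemble([table]))
result = dbscan(scaled.values, min_samples=3)
print("clusters:", result.n_clusters, "| eps:", round(result.eps, 2))
```

prints

```
 cell_id  mask_area  circularity  peaks_num_Golgi  peaks_xy_std_Golgi  dist_nuc_Golgi  objects_num_cilia
       1       3592         0.93               10               25.16            5.73                  0
       2       2870         0.91                1                0.00           25.07                  0
       3       4386         0.95               12               22.55           20.04                  1
       4       4193         0.95               16               28.41           12.25                  0
       5       1133         1.00                0                0.00             NaN                  0
clusters: 2 | eps: 5.01
```

Cell 2 has a packed Golgi: one merged peak, zero spread, and a nucleus–Golgi
center-of-mass distance of ~25 px (the generator placed it at 25).  Cells 1,
3 and 4 are dispersed/fragmented: many peaks with large spread and the Golgi
center of mass near the nucleus.  Cell 5 is mitotic — small, perfectly
round, and with no binarizable Golgi (`dist_nuc_Golgi` missing, later
median-imputed with a flag).  Clustering the scaled table separates the
population into its interphase (16 cells) and mitotic (3 cells) phenotypes
with one noise cell; checking against `truth` confirms the mapping.

The same pipeline runs from the shell:

```sh
phenoprofiler synth --seed 42 --n-cells 20 --size 700 --out-dir scene/
phenoprofiler profile scene/scene.tif --channel-map scene/channel_map.json \
    --labels scene/labels.tif --out features.csv
phenoprofiler cluster features.csv --min-samples 3 --out-dir clustered/
phenoprofiler report scene/scene.tif --labels-mask scene/labels.tif \
    --cluster-labels clustered/labels.csv --out overlay.png
```

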