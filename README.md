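# bodyquant

Volumetric quantification for whole-body light-sheet microscopy:
3D connected-component labeling and morphometry in physical units,
nearest-neighbor spatial statistics between object classes, organ-region
density summaries, filament (nerve-plexus) length-density estimation,
colocalization ratios, and staining penetration-depth profiling — plus a
synthetic phantom generator with exact ground truth so the entire
pipeline can be validated without any microscope data.

## Who this is for

Tissue-clearing and light-sheet imaging produce annotated 3D volumes of
whole organs or whole animals: one channel marking micrometastases,
another marking tertiary lymphoid structures (TLS — organized immune
aggregates that form near tumors), a nerve marker tracing the enteric
plexus, and so on. The recurring analysis questions are always the
same — *how many objects, how big, where, and how close to what?* —
but they have to be answered in anisotropic physical units (a typical
acquisition has a 10 µm z step with finer lateral sampling) and the
answers have to be reproducible bit-for-bit. bodyquant is a library and
CLI for exactly that.

## The core computations

- **Labeling.** Connected components of a binary annotation under 6-,
  18- or 26-adjacency, implemented as a single raster pass with
  union–find. Components are numbered by the raster order of their
  first voxel, so label volumes are identical across platforms.
- **Morphometry.** For each object *i* with voxel count
  $n_i$: volume $V_i = n_i\,\Delta_z\Delta_y\Delta_x / 10^9$ mm³ and
  centroid $\bar{x}_i$ = unweighted mean of member voxel centers (µm).
- **Spatial statistics.** For source class $S$ and target class $T$,
  each source gets $d_i = \min_{j \in T}\lVert \bar{x}_i - \bar{x}_j
  \rVert_2$ (ties → lowest target id; no eligible target → missing,
  excluded from summaries with counts reported). Region tables count
  objects by the organ region containing the centroid and report
  densities (count / region volume) and fractions; a Pearson or
  Spearman correlation across regions tests whether two classes
  co-distribute.
- **Filament density.** Random non-overlapping cubic subvolumes
  (default five cubes of 200 µm edge), 3D thinning to a centerline
  skeleton, length from a per-component minimum spanning structure of
  the 26-neighbor graph with physically weighted edges, density =
  length / cube volume.
- **Profiles.** Per-slice mean intensity vs depth from an entry
  surface; penetration depth = the contiguous above-threshold run from
  the surface. Group comparisons use the classical pooled two-sided
  t test (Welch and one-way ANOVA available).

The phantom generator places two object classes as non-touching
ellipsoids with log-normal volumes, optional TLS-to-metastasis
coupling, organ-region placement priors, lattice filament networks of
exactly known centerline length, and an imaging model (exponential
depth attenuation + Gaussian noise). Every placement is emitted as
ground truth, which is what the test suite checks recovery against.

## Worked example

```python
import bodyquant as bq

cfg = {"seed": 1}                       # default phantom: ~1 mm³ grid,
out = bq.run_pipeline(cfg, "run1")      # 25 metastases, 40 TLS, coupled
```

This writes volumes (TIFF + geometry sidecars), object tables (CSV) and
`summary.json` into `run1/`. With seed 1 the summary reports, among
other quantities:

| quantity | value | meaning |
|---|---|---|
| `median_distance_mm` (met→TLS) | 0.067 | median metastasis-to-nearest-TLS centroid distance |
| `median_distance_mm` (TLS→TLS) | 0.165 | median TLS-to-nearest-TLS distance |
| mean metastasis volume | 0.0028 mm³ | voxel-count volume in physical units |
| mean TLS volume | 0.00059 mm³ | TLS are several-fold smaller, as configured |
| density correlation r | 0.92 | metastasis and TLS densities co-vary across regions |

The coupled generator places each TLS near a random metastasis
(Gaussian displacement, 60 µm scale), so the met→TLS distances are much
shorter than the TLS→TLS background spacing and the per-region
densities of the two classes correlate positively — the same signature
the analysis is designed to detect in real data. Rerunning with the
same seed reproduces every output file hash exactly (see
`manifest.json`).

The same operations are available from the shell:

```sh
bodyquant run --config cfg.json --seed 1 --out run1
bodyquant label --in mask.tif --connectivity 26 --out labels.tif
bodyquant measure --labels labels.tif --class TLS --regions regions.tif --out objects.csv
bodyquant filaments --mask plexus.tif --edge-um 200 --n 5 --seed 7 --out samples.csv
bodyquant coloc --a a.tif --b b.tif --tolerance-um 0
```

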