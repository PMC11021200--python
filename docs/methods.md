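# Methods

## Conventions

Axis order is (z, y, x) throughout. Physical coordinates and spacings
are in µm; volumes are reported in mm³ (1 mm³ = 10⁹ µm³) and distances
additionally in mm at the presentation layer, matching how whole-body
figures are usually labeled. Voxel indices are 0-based; a voxel's
physical position is its center, `origin + (index + ½)·spacing`, with
the origin at the corner of voxel (0,0,0). Centroid arithmetic is then
shift-consistent: enlarging or translating the grid never moves an
object's centroid relative to its voxels.

Default spacing is (10, 6.5, 6.5) µm — a 10 µm axial step with finer
lateral sampling, the geometry typical of whole-body light-sheet
acquisition — so anisotropy is exercised by default in every
computation rather than being a special case.

## Connected components and morphometry

Labeling is a single raster pass over the binary mask: for each
foreground voxel, the backward half of the chosen neighborhood (3, 9 or
13 offsets for connectivity 6, 18, 26) is examined and equivalences are
merged with union–find (path halving). Final labels are assigned by the
raster order of each component's first voxel, making label volumes
bit-identical across platforms and runs — a deliberate contract, since
downstream tables key on label ids. Default connectivity is 26, the
common convention for blob-like objects in 3D; it is always an explicit
parameter because published analyses frequently omit it and library
defaults differ.

Morphometry is purely voxel-based: volume = voxel count × voxel volume;
centroid = unweighted mean of voxel centers (annotations, not
intensities, define objects, so intensity weighting would be spurious).
Objects touching the volume border are kept and flagged `on_border`
rather than dropped; excluding them is the caller's explicit decision.

## Nearest-neighbor statistics

All distances are centroid-to-centroid Euclidean distances in µm.
Surface-to-surface distances would need a segmentation-quality model
the data cannot support; centroids are what annotation pipelines
actually export. Ties are broken toward the lower target id. Above
1000 targets a k-d tree accelerates the search, with ties re-resolved
so results are bit-identical to brute force; the O(n·m) double loop is
retained in the test suite as the independent oracle. Sources with no
eligible neighbor (empty target class, or self-exclusion with a single
object) carry missing distances that are excluded from summaries —
never imputed — with exclusion counts reported alongside every mean.

Region membership is centroid containment in the region label volume;
centroids on background go to an explicit "none" row, so region
fractions always sum to 1. Densities are counts per region volume
(mm⁻³); the correlation of two classes' density vectors across regions
(Pearson default, Spearman optional) requires ≥ 3 regions and errors on
zero variance rather than returning NaN.

Colocalization between two binary masks is the fraction of mask-a
voxel centers within a physical tolerance of mask-b voxel centers,
computed via an exact Euclidean distance transform with per-axis
sampling. Tolerance 0 reduces to plain voxel overlap. The tolerance
exists because interactive colocalization tools rarely document their
distance convention; 0 is the reproducible baseline.

## Profiles and group comparison

An axial profile is the per-slice mean intensity ordered from a chosen
entry surface, with slice depth at the voxel center `(i + ½)·spacing`.
Penetration depth is the depth of the deepest slice such that every
slice before it is also above threshold — a contiguous staining front,
not a total above-threshold count, so a bright pocket deep in unstained
tissue does not inflate the depth. The threshold is always an explicit
input. With an exponential intensity decay `I₀e^(−λd)` and no noise the
returned depth equals the analytic crossing `ln(I₀/T)/λ` to within one
slice spacing, which is the resolution limit of any slice-wise
definition.

Two-group comparisons use the classical pooled-variance two-sided
unpaired t test; `equal_var=False` selects Welch, and one-way ANOVA is
provided for more than two groups (both conventions appear in practice
for this kind of data, so both are exposed). Two zero-variance groups
with equal means return t = 0, p = 1 rather than NaN. Results are
reported as mean ± s.d. per group.

## Filament density

Cubic subvolumes (default five cubes of 200 µm edge) are drawn
uniformly at random among fully-interior positions, without overlap
between cubes, by bounded rejection sampling; failure to place the
requested count reports the achieved maximum. Overlap-free sampling
keeps the per-cube densities closer to independent for the group test.

Centerline length is estimated by 3D thinning (scikit-image's Lee
skeletonization) followed by summing a per-component minimum spanning
structure of the skeleton's 26-neighbor graph, edges weighted by
physical center-to-center distance. The MST avoids double-counting the
chord edges that voxel skeletons produce along diagonal runs; its known
cost is that each independent cycle of a lattice loses exactly one edge
— a deterministic underestimate (one pitch length per lattice cell)
that is identical across compared conditions and therefore cancels in
contrasts. Absolute accuracy on open curves is sub-percent: a straight
4 mm tube recovers within ~0.3%, a 45° staircase within 10%, a
collinear voxel line exactly.

One numerical hazard deserves note: parallel 3D thinning annihilates
structures whose cross-section has even extent on both lateral axes (no
endpoint anchor survives the symmetric subiterations — a 4×4-voxel tube
thins to nothing). `skeletonize_mask` detects this by comparing
connected-component counts before and after thinning and, on loss,
re-thins after a one-voxel asymmetric (corner) dilation, which makes
every extent odd. The fallback skeleton can sit up to one voxel off the
original mask surface, a length perturbation far below a voxel per
branch.

## The phantom generator

The generator produces the statistical structure the analysis assumes,
with exact ground truth:

- **Objects** are axis-aligned ellipsoids; a voxel belongs to an object
  iff its center is inside. Volumes are log-normal — metastases with
  median 0.002 mm³ (log-sd 0.8), TLS with median 0.0005 mm³ (log-sd
  0.5) by default. These medians put objects at the micrometastasis
  scale (tens of µm radius) while keeping the TLS ≪ metastasis size
  ordering seen in tumor models; the extreme upper tail of real
  metastasis size distributions (single objects approaching mm³ scale)
  is deliberately not reproduced, since such objects cannot be placed
  in a desk-scale grid — analyses sensitive to that tail should not
  rely on the default phantom. Mild per-axis shape jitter (log-sd 0.1,
  volume-preserving) keeps ellipsoids from being perfect spheres.
- **Placement** enforces non-touching objects within a class (bounding
  spheres separated by at least one voxel plus the gap), so labeling an
  annotation must recover exactly the generated count — isolating
  labeling correctness from generator ambiguity. Overcrowding raises a
  named error instead of degrading silently.
- **Regions** default to named slabs along y ("lung", "gut", "other"),
  with placement priors 0.62 / 0.19 / 0.19 — a lung/gut-dominated
  dissemination pattern. Slabs are deliberate simplifications: region
  volumes are exactly known, and nothing in the analysis depends on
  organ shape, only on membership.
- **Coupling**: each TLS center is a uniformly chosen metastasis center
  plus an isotropic Gaussian displacement (default scale 60 µm), or
  region-prior placement when uncoupled. The 60 µm default puts the
  coupled median TLS-to-metastasis distance well below the uncoupled
  nearest-neighbor background spacing at the default counts, giving the
  detection tests a realistic but not trivial contrast.
- **Filaments** form a cubic lattice of tubes (nodes at a configurable
  pitch, axis-aligned edges, configurable tube radius); dropout removes
  whole edges uniformly at random, emulating a sparser, disorganized
  network. Truth records every retained edge polyline and the exact
  total centerline length.
- **Imaging model**: `clean · e^(−λ·depth) + N(0, σ)`, clipped at 0,
  with depth measured to voxel centers from a chosen entry surface —
  the same depth convention the profile code uses, so the closed-form
  checks are exact. No optical PSF, tile seams or stitching artifacts
  are simulated.

All generator output is a pure function of (config, seed): a single
seed sequence is split deterministically into per-stage streams
(metastasis placement, TLS placement, filament dropout, imaging noise),
so partial re-runs reproduce exactly.

What passing tests on phantoms do show: the measurement chain —
labeling, physical-unit morphometry, neighbor search, region
statistics, length estimation — is correct on inputs whose truth is
known, including under anisotropy and coupling. What they do not show:
robustness to segmentation errors, intensity inhomogeneity beyond the
exponential model, organ-shaped region boundaries, or touching objects
— real annotations violating the non-touching assumption will be
merged by design.

## Pipeline and problem sizes

The orchestrated run (simulate → label → measure → spatial summary)
records every output file's SHA-256 in a manifest; determinism is
tested as hash equality across runs. Configs are flat JSON with unknown
keys rejected.

Default problem sizes — a ~1 mm³ grid (100×154×154 voxels) with 25
metastases and 40 TLS for the object pipeline, 20 seed pairs for
coupling detection, 10–20 seeds of 0 vs 0.6 dropout lattices with five
200 µm cubes each for the filament contrast — were chosen so the full
validation suite exercises every code path at statistically meaningful
power while remaining comfortable to run on a laptop. All sizes are
configuration, not constants.

## Known limitations

- Watershed splitting of touching objects is out of scope; the labeling
  is purely adjacency-based.
- No edge-effect correction for nearest-neighbor statistics near organ
  or volume boundaries (border objects are flagged so callers can
  exclude them).
- Lattice cycle undercounting in skeleton length (one edge per
  independent cycle), as described above.
- Regions are boxes/slabs in the generator; real organ geometry must be
  supplied as a label volume by the user.
- Proprietary microscope formats (Imaris, Arivis) are not read; convert
  to TIFF or OME-Zarr first.
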