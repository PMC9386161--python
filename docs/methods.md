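# Methods

This note records the models, conventions and numerical choices behind
each module, what the synthetic phantom does and does not emulate, and
the known limits of the approach.

## Coordinate and intensity conventions

All volumes are `(z, y, x)` arrays — section index, row, column — and
every shape or voxel-size triple in the package uses that axis order.
Voxel centers sit at integer indices; the physical position of voxel `i`
along an axis is `i × voxel_size_um`. The default sampling,
(1.0, 0.32, 0.32) µm, matches line-scan acquisition with 0.32 µm
in-plane pixels and 1 µm sections. Intensities are 16-bit unsigned
(sCMOS range), clipped on write.

## The phantom

The generator produces the two channels a dual-color block-face
microscope would record, plus exact ground truth for every structure.

**Myocardium.** The row axis is treated as transmural depth and split by
`layer_boundaries_frac` (default thirds) into epi-, mid- and
endocardial layers whose fibers run along z, along x, and along z again
— the vertical / circumferential / vertical arrangement of the
ventricular wall. Each layer is packed with parallel cylinders
(myocytes, default radius 6 µm, 0.64 µm gaps) at flat foreground
intensity. One ellipsoidal nucleus (default axes 15.5 × 3.5 × 3.5 µm,
major axis along the fiber) is centered in each inter-disc segment of
each myocyte, at a brighter level; nuclei are only placed where the
ellipsoid fits entirely inside its own myocyte and layer, since a
nucleus straddling a cell boundary would invalidate the ground-truth
label containment. Intercalated discs are 1-voxel-thick background-dark
planes transverse to the fiber every `disc_spacing_um` (default 100 µm,
a typical cardiomyocyte length), phase-shifted by half a spacing so a
disc never coincides with the volume boundary (an unshifted comb would
blank the z = 0 section of a fiber-along-z layer).

**Vasculature.** The vessel tree is a user-supplied list of straight
`Branch` segments with children. Each segment is rasterized as a
spherocylinder (rounded caps) by exact point-to-segment distance on the
anisotropic grid. Vessels with radius above 3 in-plane voxels render as
a bright wall around a dark lumen — as an endothelial membrane label
does — with wall thickness `max(0.64 µm, 2 voxels)`; thinner vessels
render filled, since a sub-voxel wall cannot be resolved anyway.
Capillary-scale branches carry short brighter stretches of wall every
20 µm emulating elongated endothelial nuclei. The ground truth stores
the bright-voxel mask (exactly what thresholding can recover), the
centerline graph with true radii, and the branch count.

**Noise and determinism.** Both channels get i.i.d. Gaussian noise of
`noise_sd` from one `numpy` generator seeded by `spec.seed`, myocardium
first; identical spec and seed give bit-identical volumes. The flat
foreground/background intensity model is a deliberate simplification:
no optical PSF, no depth-dependent attenuation, no photobleaching, no
shot-noise intensity dependence. Consequences for interpretation are
listed under Limitations.

**Strip emission.** Each section is cut into strips of
`strip_width_px` columns sharing `overlap_px` columns with the next
strip; the last strip is anchored flush with the section edge, so its
overlap with its left neighbor can exceed the nominal value, and each
strip records the actual designed overlap with its right neighbor.
Alternate strips carry a reversed-scan flag as metadata only (pixel
order is normalized): the back-and-forth line scan is a timing fact, and
no geometric distortion model exists for it.

## Stitching

Offset estimation is exhaustive integer-pixel normalized
cross-correlation between the trailing band of the left strip and the
leading band of the right one, over ±10 columns (configurable) around
the nominal offset and ±3 rows (block-face drift between strips is
small). Sub-pixel registration is deliberately absent: the acquisition
geometry gives integer-pixel offsets, and the round-trip tests require
exactness. Two fallbacks return the nominal offset with a warning: a
zero-variance overlap band (score 0), and a best correlation below 0.2
— the expected peak correlation between independent noise bands of this
size is well under that, so a lower best score means there is no signal
to register on.

Placement is cumulative; `cut` keeps the left strip up to the midpoint
of each overlap zone (any cut point is exact when offsets are right —
the midpoint balances residual error when they are not), `feather`
blends linearly with weights summing to one. Output height is the
intersection of vertically aligned rows. A computed gap (negative
overlap) raises an error naming the pair.

## Pyramid store

Levels live in a zarr group, one chunked array per level, with voxel
size and reduction method in the attributes; chunked storage makes
region reads O(touched chunks), and levels are written one output
z-chunk-row at a time. The default reduction factor is (2, 2, 2) per
level, adding levels until the coarsest fits 256³.

Numerical choices worth stating:

- Mean reduction accumulates in float64 and rounds half-to-even before
  the uint16 cast. Partial edge blocks average only the voxels they
  contain (reduceat-based sums divided by true counts), so a constant
  field is constant at every level and the global mean drifts at most
  0.5 per level from rounding alone.
- Resampling to a coarser grid (e.g. the 10 µm whole-organ display
  grid) picks the coarsest stored level not exceeding the target on any
  axis, then interpolates trilinearly; the native-to-display ratio
  (10 / 0.32 = 31.25) is non-integer, so decimation is not an option.
  Output voxel `j` sits at `j × target`; the output covers
  `ceil(extent / target)` voxels per axis; upsampling is refused.
  Trilinear interpolation reproduces affine intensity fields exactly up
  to integer rounding (±0.5), which the tests exploit as an oracle.

## Rendering

Projections are per-pixel maxima over a slab along the axial, sagittal
or coronal axis (mapped to array axes 0, 1, 2). Channel merging windows
each channel to [0, 1], multiplies by its display color — fuchsia for
myocardium, green for vasculature — sums and clips; joint saturation
renders white since fuchsia and green cover all three primaries.

Depth coding binarizes each of the k slices of a slab (threshold given,
or Otsu on the slab histogram), samples k colors at equal intervals
along an HSV hue sweep from blue (240°) to red (0°), paints slice i with
color i, and stacks. Where several slices are foreground at one pixel
the default keeps the deepest (`last_hit`, sequential overwriting);
`first_hit` is available because either reading of "stack sequentially"
is defensible. The `slice_of_origin` map (−1 = background) is part of
the output, and every foreground pixel's color is exactly
`colormap[slice_of_origin]` — no blending, no interpolated colors.

## Vascular analysis

Segmentation is a global threshold (Otsu when automatic) plus removal of
components below `min_component_vox`; manual corrections are per-section
add/remove masks kept in a log so the final mask is always reproducible
by replaying the log over the automatic one.

Tracing flood-fills the component containing the seed (26-connectivity
by default — 6-connectivity breaks thin diagonal capillaries). Because
large vessels are hollow shells in the mask, lumens are filled before
skeletonization by slice-wise 2-D hole filling along all three axes (a
tube open at both ends is not a 3-D cavity, but its cross-section is a
2-D hole along some axis). The filled component is thinned to a
skeleton; spurs — endpoint paths shorter than 3× the local radius at
their junction — are pruned as thinning artifacts. The branch count is
the number of remaining degree-1 endpoints minus two (the trunk's own
ends), floored at zero: a straight tube counts 0, a trunk with five side
branches counts 5. This convention is well-posed for
side-branches-off-one-trunk topologies (the coronary-tracing use case);
for it to hold, junctions must keep ≳4 trunk radii of clearance from
the trunk ends, because skeletonization retracts tube ends by about one
radius and the pruning rule then needs 3 more. Per-branch radius is the
mean anisotropic distance-transform value along each endpoint-to-
junction path.

Surfaces come from marching cubes at the 0.5 level of the zero-padded
binary mask (padding closes every component; duplicate/degenerate
triangles from shared cell edges are dropped to keep the mesh
watertight), scaled to µm. Smoothing is Taubin's alternating
shrink/dilate Laplacian (λ = 0.5, µ = −0.526, 10 iterations by
default), which relaxes the voxel staircase while preserving enclosed
volume to ~1% on tubes of radius ≥ 3 voxels.

Mean curvature is the cotangent-Laplacian mean-curvature normal over
barycentric vertex areas, signed by the outward vertex normal so convex
surfaces are positive; Gaussian curvature is the angle deficit over the
same areas; the maximum principal curvature is H + √max(H² − K, 0).
On marching-cubes meshes the per-vertex estimate is noisy (irregular
triangle fans), but the median over a region is accurate to a few
percent of the closed-form values on spheres and cylinders; tests and
reported numbers therefore use region medians. Degenerate triangles are
excluded from the stencils with a warning.

Curvature coloring maps the robust [2nd, 98th] percentile range of the
signed field linearly onto the blue→red hue sweep (maximum curvature
red, minimum blue), clamping outliers; a constant field renders
mid-colormap with a warning. Signed curvature is the default; the
absolute value can be passed instead when the sign is not of interest.

## Morphometry

All measurements go through a `ScaleCalibration` (in-plane pixel pair +
section thickness), so every value is in µm or µm³ and scales linearly
(volumes cubically) with the calibration.

- Distances: Euclidean with anisotropic pixel scaling.
- Nucleus ellipse: the ellipse with the same normalized second central
  moments as the region (the ImageJ "Fit Ellipse" convention), computed
  on physically scaled pixel centers with the per-pixel continuous-
  coverage term (p²/12) added to the covariance; axes are 4√eigenvalue.
  Regions under 5 pixels are rejected. Rasterization phase limits
  accuracy to ~1–3% for minor axes near 10 pixels; the recovery study
  (50 random nuclei, axes 3–20 µm) shows median axis error well under
  3%.
- Nucleus volume: voxel count × voxel volume per label; the cohort
  summary is the unweighted mean and sample (n−1) SD. At 1 µm sections
  a 3.5 µm-thick nucleus spans only ~3 sections, so the voxel-counted
  volume depends on the grid phase by up to tens of percent; volume
  claims should be made at finer z sampling or over cohorts.
- Vessel diameter: twice the anisotropic Euclidean distance transform of
  the lumen-filled mask, read at the skeleton voxel nearest the picked
  point (reading at the centerline avoids wall-point bias); the method
  note in the result names that voxel. The distance transform measures
  to the nearest background voxel *center*, so an isolated 1-voxel-wide
  line reports two voxel extents — the convention's fixed point, stated
  rather than hidden.

## Evaluation scenarios and problem sizes

`cardiomost.benchmarks` defines the standard scenarios the acceptance
script and acceptance tests both run. Sizes are chosen so each scenario
finishes in seconds on one CPU while remaining non-trivial: stitching
uses 8 sections of 256 × 1940 px (3 strips of 660 px, 20 px overlap) at
2% noise; vascular recovery uses a 64 × 160 × 128 isotropic grid with
the five-branch tree at 5% noise; depth coding checks 1,000 random
16-slice stacks against a per-pixel brute-force scan; curvature uses
implicit-surface meshes of a 10 µm sphere, a 5 µm cylinder and a flat
plate; the end-to-end scenario runs the full pipeline twice from one
config and compares every output file byte for byte.

## What passing tests do and do not show

The phantom has flat intensities, Gaussian noise, straight vessel
segments, axis-aligned fiber layers and geometric nuclei. Passing
recovery tests therefore demonstrates the *pipeline's* correctness —
registration arithmetic, reductions, oracles, discrete geometry — under
controlled conditions, not robustness to the full texture of real
tissue: uneven staining, PSF blur, curved fibers, vessel tortuosity,
embedding artifacts. Real acquisitions may need manual edit passes
(supported and logged) and parameter tuning (thresholds, search radii,
pruning multiplier — all exposed). Inter-section registration is
intentionally absent: block-face geometry keeps sections natively
aligned, and nothing in the package compensates z misalignment.
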