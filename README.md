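# cardiomost

A toolkit for processing whole-heart, single-cell-resolution data from
block-face fluorescence microscopy. Serial sectioning microscopes of the
fMOST family image a resin-embedded mouse heart as thousands of natively
aligned 1-µm sections, each acquired as overlapping 660-µm line-scan
strips in two channels: a propidium-iodide counterstain showing the
myocardial cytoarchitecture and a transgenic GFP reporter labeling the
vascular endothelium down to ~2-µm capillaries. Between the raw strips
and a measurable 3-D data set sit a chain of processing steps, and this
package implements that chain end to end:

- **`phantom`** — a synthetic dual-channel heart generator with exact
  ground truth: cylindrical myocytes in the three transmural fiber layers
  (vertical / circumferential / vertical), brighter elliptical nuclei,
  dark intercalated-disc planes, and a branching vessel tree from
  hollow-walled trunks down to filled capillaries with endothelial
  nucleus streaks. Every downstream module is testable against it with
  no microscope and no external data.
- **`mosaic`** — strip-to-section stitching: integer-pixel normalized
  cross-correlation over the overlap band (±10 px search by default),
  then overlap removal by midpoint cut or linear feathering.
- **`pyramid`** — a chunked, multilevel-resolution volume store (zarr
  layout): exact block-mean/max reduction (round-half-to-even), region
  reads, and trilinear resampling onto arbitrary coarser grids such as
  the 10 µm display grid (a non-integer 31.25× of the 0.32 µm native
  sampling).
- **`render`** — thickness-limited maximum-intensity projections,
  fuchsia/green two-channel merges, and depth-coded projections in which
  each slice of a slab is binarized, painted with one color of a
  linearized blue→red color bar, and stacked so hue encodes depth.
- **`vasc`** — threshold segmentation with replayable manual edits, seed
  tracing with skeleton-based branch counting and per-branch radii,
  marching-cubes wall surfaces with shrink-free (Taubin) smoothing,
  discrete mean/Gaussian curvature, and curvature color-coding
  (maximum red, minimum blue).
- **`morpho`** — scale-calibrated measurements: point distances, nucleus
  ellipse axes by the equal-second-moment ("Fit Ellipse") convention,
  nucleus volumes as voxel count × voxel volume, and vessel diameters as
  twice the distance transform at the centerline.

Conventions: arrays are `(z, y, x)` = (section, row, column); all shape
and voxel-size triples use that order; voxel `i` sits at physical
position `i × voxel_size`. The default sampling is (1.0, 0.32, 0.32) µm.

## Worked example

Generate a vascular phantom — a radius-8-µm trunk with five radius-3-µm
side branches on an isotropic 1 µm grid, 5% Gaussian noise — then
segment, trace, mesh and measure it:

```python
import numpy as np
from cardiomost import phantom as ph, vasc, morpho

spec = ph.PhantomSpec(
    volume_shape_vox=(64, 160, 128), voxel_size_um=(1.0, 1.0, 1.0),
    vessel_tree=ph.five_branch_tree(), noise_sd=950.0, seed=7,
)
myo, vessels, truth = ph.generate_phantom(spec)

mask = vasc.segment_threshold(vessels, threshold="auto", min_component_vox=27,
                              voxel_size_um=spec.voxel_size_um)
print(f"Otsu threshold: {mask.threshold_used:.0f}")

seed_vox = tuple(int(v) for v in np.argwhere(mask.mask)[0])
report, traced = vasc.trace_from_seed(mask, seed_vox)
print(f"traced component: {report.component_voxel_count} voxels, "
      f"{report.branch_count} branches")
print("branch mean radii (um):", [round(r, 2) for r in report.branch_mean_radius_um])

mesh = vasc.extract_surface(
    vasc.VesselMask(vasc.fill_lumens(traced), spec.voxel_size_um),
    smoothing_iterations=10,
)
h = vasc.vertex_curvature(mesh, kind="mean")
print(f"surface: {len(mesh.vertices)} vertices, watertight={mesh.is_watertight}")
print(f"median wall curvature: {np.median(h):.3f} /um")
```

which prints:

```
Otsu threshold: 6257
traced component: 20065 voxels, 5 branches
branch mean radii (um): [3.17, 3.17, 8.04, 8.04, 3.21, 3.21, 3.21]
surface: 15862 vertices, watertight=True
median wall curvature: 0.126 /um
```

The automatic threshold lands between background (1000) and foreground
(20000); the trace counts exactly the five side branches (the two
8-µm entries are the trunk's own ends, excluded from the count); the
recovered radii sit within a fifth of a voxel of the true 3 µm and 8 µm;
and the median wall curvature is bracketed by the analytic values for
the trunk (1/2r ≈ 0.06 /µm) and the branches (≈ 0.17 /µm).

The same flow runs from a shell:

```sh
cardiomost phantom generate --out ph --seed 3 --shape 8,256,1980 --strip-width 660
cardiomost mosaic stitch --strips ph/strips --out sections
cardiomost pyramid build --sections sections --channel vasculature --out store.zarr
cardiomost render depthcode --store store.zarr --out depth.png
```

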