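"""Standard evaluation scenarios for the whole pipeline.

Each function builds a phantom (or analytic object) under the study
conditions, runs the pipeline operation under test, and returns the
measured quantities with the problem size used.  The acceptance script
and the acceptance test suite both run these, so the reported numbers
are always recomputed from scratch.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import trimesh
from skimage.measure import marching_cubes

from . import morpho, mosaic, pipeline, pyramid, render, vasc
from . import phantom as ph

FOREGROUND = 20000
BACKGROUND = 1000
DYNAMIC_RANGE = FOREGROUND - BACKGROUND


def stitching_roundtrip(seed: int) -> dict:
    """Offset recovery on noisy strips and bit-exact restitching on
    noise-free ones: sections of 3 x 660-px strips, 20-px overlap, 256
    rows, noise at 2% of the foreground-background contrast."""
    noisy = ph.PhantomSpec(
        volume_shape_vox=(8, 256, 1940), noise_sd=0.02 * DYNAMIC_RANGE, seed=seed
    )
    myo, _, truth = ph.generate_phantom(noisy)
    per_sec = ph.emit_strips(myo, 660, 20, truth=truth)
    total = exact = 0
    for z, strips in enumerate(per_sec):
        offs = truth.strip_offsets[("myocardium", z)]
        for i, (a, b) in enumerate(zip(strips, strips[1:])):
            d_row, d_col, _ = mosaic.estimate_offset(a, b)
            want = (offs[i + 1][0] - offs[i][0], offs[i + 1][1] - offs[i][1])
            exact += (d_row, d_col) == want
            total += 1

    clean = ph.PhantomSpec(volume_shape_vox=(4, 256, 1940), noise_sd=0.0, seed=seed + 1)
    myo0, _, truth0 = ph.generate_phantom(clean)
    per_sec0 = ph.emit_strips(myo0, 660, 20, truth=truth0)
    max_err = 0
    for z, strips in enumerate(per_sec0):
        sec = mosaic.stitch_section(strips, [(0, 640), (0, 640)], policy="cut")
        max_err = max(max_err, int(np.abs(sec.pixels.astype(int) - myo0[z].astype(int)).max()))
    return {
        "offset_recovery_pct": 100.0 * exact / total,
        "restitch_max_abs_error": float(max_err),
        "n_pairs": total,
    }


def pyramid_integrity(seed: int) -> dict:
    """Level-0 read-back, mean preservation across levels, and affine
    fidelity of resampling onto a non-integer-ratio grid."""
    rng = np.random.default_rng(seed)
    vol = rng.integers(0, 60000, size=(32, 48, 56)).astype(np.uint16)
    p = pyramid.build_pyramid(vol, chunk_shape_vox=(16, 16, 16), n_levels=3)
    level0_err = float(np.abs(p.read_full(0).astype(int) - vol.astype(int)).max())
    mean_dev = max(
        abs(float(p.read_full(l).mean()) - float(vol.mean())) for l in (1, 2)
    )

    ramp = np.broadcast_to(
        (np.arange(100, dtype=np.float64) * 100).astype(np.uint16), (4, 32, 100)
    ).copy()
    pr = pyramid.build_pyramid(ramp, voxel_size_um=(1.0, 0.32, 0.32))
    res = pr.resample_to_voxel((1.3, 0.5, 0.45))
    x = np.arange(res.data.shape[2]) * 0.45 / 0.32
    interior = x <= 99
    ramp_err = float(
        np.abs(res.data[..., interior].astype(np.float64) - x[interior] * 100).max()
    )
    return {
        "level0_roundtrip_max_abs_error": level0_err,
        "mean_reduction_max_mean_deviation": mean_dev,
        "ramp_resample_max_error": ramp_err,
        "n_voxels": int(vol.size),
    }


def depth_code_agreement(seed: int, n_stacks: int = 1000) -> dict:
    """Exhaustive agreement with a per-pixel brute-force scan on random
    binary stacks, both overwrite orders."""
    rng = np.random.default_rng(seed)
    agree = total = 0
    for _ in range(n_stacks):
        stack = (rng.random((16, 8, 8)) < 0.35).astype(np.uint16) * 200
        fg = stack >= 100
        for order in ("first_hit", "last_hit"):
            dci = render.depth_code(list(stack), threshold=100, order=order)
            k, h, w = fg.shape
            for y in range(h):
                for x in range(w):
                    hits = [i for i in range(k) if fg[i, y, x]]
                    want = (hits[-1] if order == "last_hit" else hits[0]) if hits else -1
                    agree += int(dci.slice_of_origin[y, x]) == want
                    total += 1
    return {"depthcode_oracle_agreement_pct": 100.0 * agree / total, "n_stacks": n_stacks}


def mip_agreement(seed: int, n_volumes: int = 200) -> dict:
    """Element-wise max against a slice-by-slice oracle plus slice-
    permutation invariance on random volumes."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_volumes):
        vol = rng.integers(0, 60000, size=(10, 12, 12)).astype(np.uint16)
        start, thick = 2, 6
        mip = render.max_projection(
            vol, render.ProjectionSpec(start_index=start, thickness_slices=thick)
        )
        oracle = vol[start]
        for i in range(start + 1, start + thick):
            oracle = np.maximum(oracle, vol[i])
        perm = vol[rng.permutation(10)]
        spec = render.ProjectionSpec(thickness_slices=10)
        invariant = np.array_equal(
            render.max_projection(vol, spec), render.max_projection(perm, spec)
        )
        ok += np.array_equal(mip, oracle) and invariant
    return {"mip_oracle_agreement_pct": 100.0 * ok / n_volumes, "n_volumes": n_volumes}


def _sdf_mesh(f, lo, hi, n):
    ax = [np.linspace(l, h, n) for l, h in zip(lo, hi)]
    grids = np.meshgrid(*ax, indexing="ij")
    spacing = [(h - l) / (n - 1) for l, h in zip(lo, hi)]
    verts, faces, _, _ = marching_cubes(f(*grids), level=0.0, spacing=spacing)
    tm = trimesh.Trimesh(verts + np.asarray(lo), faces, process=True, validate=True)
    return vasc.SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def curvature_analytics() -> dict:
    """Discrete mean curvature against closed forms: a 10-um sphere
    (H = 1/r), the mid-section of a 5-um cylinder (H = 1/2r), and a flat
    plate (H = 0)."""
    sphere = _sdf_mesh(
        lambda z, y, x: np.sqrt(z**2 + y**2 + x**2) - 10.0, (-13,) * 3, (13,) * 3, 53
    )
    h_sphere = float(np.median(vasc.vertex_curvature(sphere, "mean")))

    cyl = _sdf_mesh(
        lambda z, y, x: np.maximum(np.sqrt(y**2 + x**2) - 5.0, np.abs(z) - 30.0),
        (-35, -8, -8), (35, 8, 8), 71,
    )
    h_cyl_all = vasc.vertex_curvature(cyl, "mean")
    mid = np.abs(cyl.vertices[:, 0]) < 15
    h_cyl = float(np.median(h_cyl_all[mid]))

    box = _sdf_mesh(
        lambda z, y, x: np.maximum.reduce(
            [np.abs(z) - 10, np.abs(y) - 10, np.abs(x) - 10]
        ),
        (-13,) * 3, (13,) * 3, 53,
    )
    h_box = vasc.vertex_curvature(box, "mean")
    v = box.vertices
    flat = (np.abs(v[:, 0] - 10) < 0.2) & (np.abs(v[:, 1]) < 7) & (np.abs(v[:, 2]) < 7)
    return {
        "sphere_mean_curvature_per_um": h_sphere,
        "sphere_curvature_error_pct": abs(h_sphere - 0.1) / 0.1 * 100.0,
        "cylinder_mid_curvature_per_um": h_cyl,
        "cylinder_curvature_error_pct": abs(h_cyl - 0.1) / 0.1 * 100.0,
        "plate_max_abs_curvature_per_um": float(np.abs(h_box[flat]).max()),
        "n_vertices": int(len(sphere.vertices)),
    }


def vascular_recovery(seed: int) -> dict:
    """Trunk (radius 8 voxels, hollow wall) with five side branches
    (radius 3 voxels) on an isotropic 1-um grid, noise at 5% of contrast,
    automatic threshold: Dice against the true mask and branch count."""
    spec = ph.PhantomSpec(
        volume_shape_vox=(64, 160, 128),
        voxel_size_um=(1.0, 1.0, 1.0),
        vessel_tree=ph.five_branch_tree(),
        noise_sd=0.05 * DYNAMIC_RANGE,
        seed=seed,
    )
    _, channel, truth = ph.generate_phantom(spec)
    mask = vasc.segment_threshold(
        channel, threshold="auto", min_component_vox=27, voxel_size_um=spec.voxel_size_um
    )
    dice = 2.0 * np.logical_and(mask.mask, truth.vessel_mask).sum() / (
        mask.mask.sum() + truth.vessel_mask.sum()
    )
    seed_vox = tuple(int(v) for v in np.argwhere(mask.mask)[0])
    report, _ = vasc.trace_from_seed(mask, seed_vox)
    return {
        "vessel_dice": float(dice),
        "branch_count": float(report.branch_count),
        "n_mask_voxels": int(mask.mask.sum()),
    }


def morphometry_recovery(seed: int) -> dict:
    """Nucleus-scale ellipse axes (15.5 / 3.5 um), ellipsoid volume,
    capillary diameter, and the 50-random-nucleus axis study."""
    cal = morpho.ScaleCalibration(pixel_size_um=(0.32, 0.32), section_thickness_um=1.0)

    def ellipse_mask(semi_a, semi_b, angle_deg):
        n = int(np.ceil(2 * semi_a / 0.32)) + 16
        yy, xx = np.mgrid[0:n, 0:n]
        y = (yy - n // 2) * 0.32
        x = (xx - n // 2) * 0.32
        a = np.deg2rad(angle_deg)
        u = x * np.cos(a) + y * np.sin(a)
        v = -x * np.sin(a) + y * np.cos(a)
        return (u / semi_a) ** 2 + (v / semi_b) ** 2 <= 1.0

    major, minor, _ = morpho.fit_nucleus_ellipse(ellipse_mask(7.75, 1.75, 0.0), cal)

    zz, yy, xx = np.mgrid[0:20, 0:80, 0:80]
    z = (zz - 10) * 1.0
    y = (yy - 40) * 0.32
    x = (xx - 40) * 0.32
    lab = (((x / 7.75) ** 2 + (y / 1.75) ** 2 + (z / 1.75) ** 2) <= 1).astype(int)
    _, vol_mean, _ = morpho.nucleus_volume(lab, cal)
    analytic = 4.0 / 3.0 * np.pi * 7.75 * 1.75 * 1.75

    tree = [
        ph.Branch(start_um=(2.0, 32 * 0.32, 32 * 0.32), direction=(1, 0, 0),
                  length_um=36.0, radius_um=1.0)
    ]
    spec = ph.PhantomSpec(volume_shape_vox=(40, 64, 64), vessel_tree=tree, noise_sd=0.0)
    _, _, truth = ph.generate_phantom(spec)
    mask = vasc.VesselMask(truth.vessel_mask, voxel_size_um=spec.voxel_size_um)
    fg = np.argwhere(truth.vessel_mask)
    pt = tuple(int(v) for v in fg[len(fg) // 2])
    diameter, _ = morpho.vessel_diameter(mask, pt)

    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(50):
        a = rng.uniform(3.0, 20.0)
        b = rng.uniform(3.0, a)
        got_a, got_b, _ = morpho.fit_nucleus_ellipse(
            ellipse_mask(a / 2, b / 2, rng.uniform(0, 180)), cal
        )
        errors.append(abs(got_a - a) / a * 100)
        errors.append(abs(got_b - b) / b * 100)

    return {
        "nucleus_major_axis_um": float(major),
        "nucleus_minor_axis_um": float(minor),
        "nucleus_volume_um3": float(vol_mean),
        "nucleus_volume_error_pct": abs(vol_mean - analytic) / analytic * 100.0,
        "capillary_diameter_um": float(diameter),
        "axis_recovery_median_error_pct": float(np.median(errors)),
        "n_random_nuclei": 50,
    }


def end_to_end(seed: int, work_dir) -> dict:
    """Full pipeline from one config, twice, hashing every output byte."""
    cfg = {
        "phantom": {
            "volume_shape_vox": (16, 128, 192),
            "disc_spacing_um": 30.0,
            "noise_sd": 0.02 * DYNAMIC_RANGE,
        },
        "strips": {"width_px": 80, "overlap_px": 16},
        "pyramid": {"chunk_shape_vox": (8, 64, 64)},
    }
    work_dir = Path(work_dir)
    hashes = []
    for run in ("a", "b"):
        out = work_dir / run
        pipeline.run_pipeline(cfg, out, seed=seed)
        h = hashlib.sha256()
        for p in sorted(out.rglob("*")):
            if p.is_file():
                h.update(str(p.relative_to(out)).encode())
                h.update(p.read_bytes())
        hashes.append(h.hexdigest())
    n_files = sum(1 for p in (work_dir / "a").rglob("*") if p.is_file())
    return {
        "runs_byte_identical": float(hashes[0] == hashes[1]),
        "n_output_files": n_files,
    }
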