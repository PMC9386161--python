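"""Vessel segmentation, tracing, surfaces and curvature."""

import numpy as np
import pytest

from cardiomost import phantom as ph
from cardiomost import vasc


def dice(a, b):
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


class TestSegmentThreshold:
    def test_midway_threshold_recovers_ground_truth_exactly(self, vessel_phantom_clean):
        spec, (_, channel, truth) = vessel_phantom_clean
        mid = (spec.background_level + spec.foreground_level) / 2
        mask = vasc.segment_threshold(channel, threshold=mid, voxel_size_um=spec.voxel_size_um)
        assert np.array_equal(mask.mask, truth.vessel_mask)
        assert mask.threshold_used == mid

    def test_threshold_above_max_gives_empty_mask_with_warning(self):
        vol = np.full((4, 4, 4), 100, dtype=np.uint16)
        with pytest.warns(UserWarning, match="empty"):
            mask = vasc.segment_threshold(vol, threshold=1e6)
        assert not mask.mask.any()

    def test_auto_threshold_on_noisy_phantom_reaches_dice_095(self, vessel_phantom):
        spec, (_, channel, truth) = vessel_phantom
        mask = vasc.segment_threshold(
            channel, threshold="auto", min_component_vox=27,
            voxel_size_um=spec.voxel_size_um,
        )
        assert dice(mask.mask, truth.vessel_mask) >= 0.95


class TestManualEdits:
    def test_empty_edit_list_is_identity(self):
        m = vasc.VesselMask(np.zeros((2, 4, 4), dtype=bool))
        out = vasc.apply_manual_edits(m, [])
        assert np.array_equal(out.mask, m.mask)

    def test_add_then_remove_restores_original(self):
        rng = np.random.default_rng(0)
        m = vasc.VesselMask(rng.random((3, 8, 8)) < 0.3)
        region = np.zeros((8, 8), dtype=bool)
        region[2:5, 2:5] = True
        # removing after adding leaves exactly the voxels outside the region
        out = vasc.apply_manual_edits(m, [(1, "add", region), (1, "remove", region)])
        expect = m.mask.copy()
        expect[1] &= ~region
        assert np.array_equal(out.mask, expect)
        assert len(out.manual_edit_log) == 2

    def test_identical_edit_twice_is_idempotent(self):
        m = vasc.VesselMask(np.zeros((2, 6, 6), dtype=bool))
        region = np.zeros((6, 6), dtype=bool)
        region[1:3, 1:3] = True
        once = vasc.apply_manual_edits(m, [(0, "add", region)])
        twice = vasc.apply_manual_edits(once, [(0, "add", region)])
        assert np.array_equal(once.mask, twice.mask)

    def test_replaying_the_log_reproduces_the_mask(self):
        rng = np.random.default_rng(1)
        auto = vasc.VesselMask(rng.random((3, 8, 8)) < 0.4)
        edits = [
            (0, "add", rng.random((8, 8)) < 0.2),
            (2, "remove", rng.random((8, 8)) < 0.2),
            (1, "add", rng.random((8, 8)) < 0.1),
        ]
        final = vasc.apply_manual_edits(auto, edits)
        replayed = vasc.apply_manual_edits(
            vasc.VesselMask(auto.mask.copy()), final.manual_edit_log
        )
        assert np.array_equal(replayed.mask, final.mask)

    def test_out_of_range_section_rejected(self):
        m = vasc.VesselMask(np.zeros((2, 4, 4), dtype=bool))
        with pytest.raises(ValueError, match="out of range"):
            vasc.apply_manual_edits(m, [(5, "add", np.ones((4, 4), dtype=bool))])


def straight_tube_mask(shape=(16, 48, 16), radius=3.0):
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    return (zz - 8) ** 2 + (xx - 8) ** 2 <= radius**2


class TestTraceFromSeed:
    def test_straight_tube_has_no_branches(self):
        mask = vasc.VesselMask(straight_tube_mask(), voxel_size_um=(1, 1, 1))
        report, traced = vasc.trace_from_seed(mask, (8, 20, 8))
        assert report.branch_count == 0
        assert np.array_equal(traced, mask.mask)

    def test_five_branch_tree_counts_five(self, vessel_phantom):
        spec, (_, channel, truth) = vessel_phantom
        mask = vasc.segment_threshold(
            channel, threshold="auto", min_component_vox=27,
            voxel_size_um=spec.voxel_size_um,
        )
        seed = tuple(int(v) for v in np.argwhere(mask.mask)[0])
        report, _ = vasc.trace_from_seed(mask, seed)
        assert report.branch_count == 5
        assert report.component_voxel_count == int(
            vasc.trace_from_seed(mask, seed)[1].sum()
        )

    def test_recovered_radii_match_tree_radii(self, vessel_phantom_clean):
        spec, (_, _, truth) = vessel_phantom_clean
        mask = vasc.VesselMask(truth.vessel_mask, voxel_size_um=spec.voxel_size_um)
        seed = tuple(int(v) for v in np.argwhere(mask.mask)[0])
        report, _ = vasc.trace_from_seed(mask, seed)
        radii = sorted(report.branch_mean_radius_um)
        # five branch tips near 3 um and the two trunk ends near 8 um
        assert len(radii) == 7
        assert all(abs(r - 3.0) < 1.0 for r in radii[:5])
        assert all(abs(r - 8.0) < 1.5 for r in radii[5:])

    def test_disjoint_tube_is_not_traced(self):
        m = straight_tube_mask().copy()
        other = np.zeros_like(m)
        other[2:5, 5:40, 2:5] = True
        m2 = m | other
        mask = vasc.VesselMask(m2, voxel_size_um=(1, 1, 1))
        _, traced = vasc.trace_from_seed(mask, (8, 20, 8))
        assert not (traced & other).any()
        assert (traced == m).all()

    def test_seed_independence_within_component(self, vessel_phantom_clean):
        spec, (_, _, truth) = vessel_phantom_clean
        mask = vasc.VesselMask(truth.vessel_mask, voxel_size_um=spec.voxel_size_um)
        fg = np.argwhere(mask.mask)
        r1, t1 = vasc.trace_from_seed(mask, tuple(int(v) for v in fg[0]))
        r2, t2 = vasc.trace_from_seed(mask, tuple(int(v) for v in fg[len(fg) // 2]))
        assert r1.branch_count == r2.branch_count
        assert np.array_equal(t1, t2)

    def test_background_seed_names_nearest_foreground(self):
        mask = vasc.VesselMask(straight_tube_mask(), voxel_size_um=(1, 1, 1))
        with pytest.raises(ValueError, match="nearest foreground"):
            vasc.trace_from_seed(mask, (0, 0, 0))


class TestExtractSurface:
    def test_ball_volume_within_five_percent(self):
        zz, yy, xx = np.mgrid[0:40, 0:40, 0:40]
        ball = (zz - 20) ** 2 + (yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2
        mesh = vasc.extract_surface(
            vasc.VesselMask(ball, voxel_size_um=(1, 1, 1)), smoothing_iterations=10
        )
        assert mesh.is_watertight
        analytic = 4.0 / 3.0 * np.pi * 15**3
        assert abs(mesh.enclosed_volume_um3 - analytic) / analytic < 0.05

    def test_single_voxel_is_a_small_closed_polyhedron(self):
        one = np.zeros((3, 3, 3), dtype=bool)
        one[1, 1, 1] = True
        mesh = vasc.extract_surface(vasc.VesselMask(one, (1, 1, 1)), smoothing_iterations=0)
        assert mesh.is_watertight
        assert len(mesh.vertices) <= 8

    def test_box_mesh_bounds_the_box_within_one_voxel(self):
        box = np.zeros((10, 12, 14), dtype=bool)
        box[2:8, 3:9, 4:10] = True
        mesh = vasc.extract_surface(vasc.VesselMask(box, (1, 1, 1)), smoothing_iterations=0)
        lo, hi = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
        assert np.all(lo >= np.array([2, 3, 4]) - 1)
        assert np.all(hi <= np.array([7, 8, 9]) + 1)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            vasc.extract_surface(vasc.VesselMask(np.zeros((3, 3, 3), dtype=bool)))

    @pytest.mark.parametrize("radius", [3, 5])
    def test_tube_volume_recovered_within_ten_percent(self, radius):
        """Segmentation -> lumen fill -> surface -> enclosed volume recovers
        the analytic spherocylinder volume for radii >= 3 voxels."""
        r, length = float(radius), 50.0
        tree = [ph.Branch(start_um=(radius + 6, 10, radius + 6), direction=(0, 1, 0),
                          length_um=length, radius_um=r)]
        spec = ph.PhantomSpec(
            volume_shape_vox=(2 * radius + 12, 74, 2 * radius + 12),
            voxel_size_um=(1, 1, 1), vessel_tree=tree, noise_sd=0.0,
        )
        _, channel, _ = ph.generate_phantom(spec)
        mask = vasc.segment_threshold(channel, threshold=10000, voxel_size_um=(1, 1, 1))
        filled = vasc.fill_lumens(mask.mask)
        mesh = vasc.extract_surface(
            vasc.VesselMask(filled, (1, 1, 1)), smoothing_iterations=10
        )
        analytic = np.pi * r * r * length + 4.0 / 3.0 * np.pi * r**3  # rounded caps
        assert abs(mesh.enclosed_volume_um3 - analytic) / analytic < 0.10


class TestCurvature:
    def test_sphere_mean_curvature_is_inverse_radius(self, sphere_mesh):
        h = vasc.vertex_curvature(sphere_mesh, "mean")
        assert np.all(h > 0)  # convex outward everywhere
        assert abs(np.median(h) - 0.1) / 0.1 < 0.10

    def test_sphere_gaussian_curvature_is_inverse_radius_squared(self, sphere_mesh):
        k = vasc.vertex_curvature(sphere_mesh, "gaussian")
        assert abs(np.median(k) - 0.01) / 0.01 < 0.15

    def test_cylinder_mid_section_is_half_inverse_radius(self, cylinder_mesh):
        h = vasc.vertex_curvature(cylinder_mesh, "mean")
        mid = np.abs(cylinder_mesh.vertices[:, 0]) < 15
        assert abs(np.median(h[mid]) - 0.1) / 0.1 < 0.15

    def test_flat_plate_has_negligible_mean_curvature(self, box_mesh):
        h = vasc.vertex_curvature(box_mesh, "mean")
        v = box_mesh.vertices
        flat = (
            (np.abs(v[:, 0] - 10) < 0.2) & (np.abs(v[:, 1]) < 7) & (np.abs(v[:, 2]) < 7)
        )
        assert flat.sum() > 100
        assert np.abs(h[flat]).max() < 0.01

    def test_max_principal_on_cylinder_is_inverse_radius(self, cylinder_mesh):
        k1 = vasc.vertex_curvature(cylinder_mesh, "max_principal")
        mid = np.abs(cylinder_mesh.vertices[:, 0]) < 15
        assert abs(np.median(k1[mid]) - 0.2) / 0.2 < 0.2

    def test_open_mesh_rejected(self):
        tri = vasc.SurfaceMesh(
            vertices=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
            triangles=np.array([[0, 1, 2]]),
        )
        with pytest.raises(ValueError, match="watertight"):
            vasc.vertex_curvature(tri)


class TestColorize:
    def test_two_valued_field_maps_to_pure_blue_and_red(self, sphere_mesh):
        mesh = vasc.SurfaceMesh(sphere_mesh.vertices, sphere_mesh.triangles)
        mesh.curvature = np.where(
            np.arange(len(mesh.vertices)) % 2 == 0, 0.05, 0.25
        )
        rgb = vasc.colorize_curvature(mesh)
        assert {tuple(c) for c in rgb} == {(0, 0, 255), (255, 0, 0)}

    def test_constant_field_is_uniform_mid_color_with_warning(self, sphere_mesh):
        mesh = vasc.SurfaceMesh(sphere_mesh.vertices, sphere_mesh.triangles)
        mesh.curvature = np.full(len(mesh.vertices), 0.1)
        with pytest.warns(UserWarning, match="constant"):
            rgb = vasc.colorize_curvature(mesh)
        assert len(np.unique(rgb, axis=0)) == 1

    def test_thin_branch_renders_redder_than_trunk(self, vessel_phantom_clean):
        spec, (_, _, truth) = vessel_phantom_clean
        filled = vasc.fill_lumens(truth.vessel_mask)
        mesh = vasc.extract_surface(
            vasc.VesselMask(filled, spec.voxel_size_um), smoothing_iterations=10
        )
        h = vasc.vertex_curvature(mesh, "mean")
        rgb = vasc.colorize_curvature(mesh)
        v = mesh.vertices
        on_trunk = (np.abs(v[:, 2] - 64) < 10) & (np.abs(v[:, 0] - 32) < 10)
        on_branch = np.abs(v[:, 2] - 64) > 30
        # 1/r ordering: the thin branch walls curve more than the trunk,
        # so they sit farther toward the red (less blue) end of the bar
        assert np.median(h[on_branch]) > 1.5 * np.median(h[on_trunk])
        assert np.median(rgb[on_branch, 2]) < np.median(rgb[on_trunk, 2])

    def test_requires_curvature_field(self, sphere_mesh):
        mesh = vasc.SurfaceMesh(sphere_mesh.vertices, sphere_mesh.triangles)
        with pytest.raises(ValueError, match="curvature"):
            vasc.colorize_curvature(mesh)


def test_mesh_export_roundtrip(tmp_path, sphere_mesh):
    import trimesh

    vasc.vertex_curvature(sphere_mesh, "mean")
    vasc.colorize_curvature(sphere_mesh)
    ply = tmp_path / "mesh.ply"
    sphere_mesh.export(ply)
    back = trimesh.load(ply)
    assert len(back.vertices) == len(sphere_mesh.vertices)
    obj = tmp_path / "mesh.obj"
    sphere_mesh.export(obj)
    assert obj.stat().st_size > 0
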