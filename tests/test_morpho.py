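"""Calibrated distance, ellipse, volume and diameter measurements."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomost import morpho, vasc
from cardiomost import phantom as ph
from cardiomost.morpho import ScaleCalibration


def rasterized_ellipse(semi_a, semi_b, angle_deg, pixel=(0.32, 0.32), margin=8):
    n = int(np.ceil(2 * semi_a / min(pixel))) + 2 * margin
    yy, xx = np.mgrid[0:n, 0:n]
    y = (yy - n // 2) * pixel[0]  # center on a pixel
    x = (xx - n // 2) * pixel[1]
    a = np.deg2rad(angle_deg)
    u = x * np.cos(a) + y * np.sin(a)
    v = -x * np.sin(a) + y * np.cos(a)
    return (u / semi_a) ** 2 + (v / semi_b) ** 2 <= 1.0


class TestMeasureDistance:
    @pytest.mark.parametrize(
        "p0, p1, pixel, expect",
        [
            ((0, 0), (0, 10), (0.32, 0.32), 3.2),
            ((0, 0), (3, 4), (1.0, 1.0), 5.0),
            ((0, 0), (3, 4), (0.32, 1.0), np.hypot(3 * 0.32, 4 * 1.0)),
        ],
    )
    def test_known_distances(self, p0, p1, pixel, expect):
        cal = ScaleCalibration(pixel_size_um=pixel)
        assert morpho.measure_distance(p0, p1, cal) == pytest.approx(expect)

    def test_identical_points_warn_and_return_zero(self):
        with pytest.warns(UserWarning, match="coincide"):
            d = morpho.measure_distance((2, 2), (2, 2), ScaleCalibration())
        assert d == 0.0

    def test_points_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            morpho.measure_distance(
                (0, 0), (10, 10), ScaleCalibration(), image=np.zeros((5, 5))
            )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        p=st.tuples(st.integers(0, 50), st.integers(0, 50)),
        q=st.tuples(st.integers(0, 50), st.integers(0, 50)),
        scale=st.floats(0.1, 5.0),
    )
    def test_distance_scales_linearly_with_calibration(self, p, q, scale):
        base = ScaleCalibration(pixel_size_um=(0.5, 0.5))
        doubled = ScaleCalibration(pixel_size_um=(0.5 * scale, 0.5 * scale))
        d0 = morpho.measure_distance(p, q, base)
        d1 = morpho.measure_distance(p, q, doubled)
        assert d1 == pytest.approx(scale * d0, rel=1e-9, abs=1e-12)


class TestFitNucleusEllipse:
    def test_reported_nucleus_axes_recovered_within_two_percent(self):
        """A 15.5 x 3.5 um ellipse at 0.32-um pixels — the axis scale of a
        cardiomyocyte nucleus — is recovered within 2%."""
        mask = rasterized_ellipse(7.75, 1.75, 0.0)
        major, minor, _ = morpho.fit_nucleus_ellipse(mask, ScaleCalibration())
        assert abs(major - 15.5) / 15.5 < 0.02
        assert abs(minor - 3.5) / 3.5 < 0.02

    def test_circle_axes_equal_diameter(self):
        mask = rasterized_ellipse(5.0, 5.0, 0.0)
        major, minor, _ = morpho.fit_nucleus_ellipse(mask, ScaleCalibration())
        assert abs(major - 10.0) <= 0.32
        assert abs(minor - 10.0) <= 0.32
        assert major >= minor

    def test_rotation_equivariance(self):
        cal = ScaleCalibration()
        m0 = rasterized_ellipse(7.75, 1.75, 0.0)
        m37 = rasterized_ellipse(7.75, 1.75, 37.0)
        maj0, min0, ang0 = morpho.fit_nucleus_ellipse(m0, cal)
        maj1, min1, ang1 = morpho.fit_nucleus_ellipse(m37, cal)
        assert maj1 == pytest.approx(maj0, rel=0.02)
        assert min1 == pytest.approx(min0, rel=0.02)
        assert abs(abs(ang1 - ang0) - 37.0) <= 1.0

    def test_translation_invariance(self):
        cal = ScaleCalibration()
        mask = rasterized_ellipse(4.0, 2.0, 20.0)
        shifted = np.roll(mask, (3, 5), axis=(0, 1))
        assert morpho.fit_nucleus_ellipse(mask, cal)[:2] == pytest.approx(
            morpho.fit_nucleus_ellipse(shifted, cal)[:2]
        )

    def test_tiny_region_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4, 4:7] = True
        with pytest.raises(ValueError, match="at least 5"):
            morpho.fit_nucleus_ellipse(mask, ScaleCalibration())

    def test_median_axis_error_under_three_percent_over_50_random_nuclei(self):
        rng = np.random.default_rng(12345)
        cal = ScaleCalibration()
        errors = []
        for _ in range(50):
            major = rng.uniform(3.0, 20.0)
            minor = rng.uniform(3.0, major)
            angle = rng.uniform(0.0, 180.0)
            mask = rasterized_ellipse(major / 2, minor / 2, angle)
            got_major, got_minor, _ = morpho.fit_nucleus_ellipse(mask, cal)
            errors.append(abs(got_major - major) / major * 100)
            errors.append(abs(got_minor - minor) / minor * 100)
        assert np.median(errors) < 3.0


class TestNucleusVolume:
    def test_single_voxel_volume(self):
        lab = np.zeros((2, 2, 2), dtype=int)
        lab[0, 0, 0] = 1
        cal = ScaleCalibration(pixel_size_um=(0.32, 0.32), section_thickness_um=1.0)
        volumes, mean, sd = morpho.nucleus_volume(lab, cal)
        assert volumes[1] == pytest.approx(0.1024)
        assert mean == pytest.approx(0.1024) and sd == 0.0

    def test_rasterized_ellipsoid_matches_analytic_volume(self):
        cal = ScaleCalibration(pixel_size_um=(0.32, 0.32), section_thickness_um=1.0)
        zz, yy, xx = np.mgrid[0:20, 0:80, 0:80]
        z = (zz - 10) * 1.0
        y = (yy - 40) * 0.32
        x = (xx - 40) * 0.32
        lab = (((x / 7.75) ** 2 + (y / 1.75) ** 2 + (z / 1.75) ** 2) <= 1).astype(int)
        _, mean, _ = morpho.nucleus_volume(lab, cal)
        analytic = 4.0 / 3.0 * np.pi * 7.75 * 1.75 * 1.75
        assert abs(mean - analytic) / analytic < 0.05

    def test_identical_cohort_has_zero_sd(self):
        lab = np.zeros((5, 6, 6), dtype=int)
        for i in range(5):
            lab[i, 2:4, 2:4] = i + 1
        cal = ScaleCalibration(pixel_size_um=(1.0, 1.0), section_thickness_um=1.0)
        volumes, mean, sd = morpho.nucleus_volume(lab, cal)
        assert len(volumes) == 5
        assert sd == 0.0 and mean == pytest.approx(4.0)

    def test_missing_labels_are_skipped_with_warning(self):
        lab = np.zeros((2, 4, 4), dtype=int)
        lab[0, 0, 0] = 1
        lab[1, 1, 1] = 3
        with pytest.warns(UserWarning, match=r"\[2\]"):
            volumes, _, _ = morpho.nucleus_volume(lab, ScaleCalibration())
        assert set(volumes) == {1, 3}

    def test_volume_scales_cubically_with_calibration(self):
        lab = (np.random.default_rng(0).random((6, 6, 6)) < 0.5).astype(int)
        c1 = ScaleCalibration(pixel_size_um=(1.0, 1.0), section_thickness_um=1.0)
        c2 = ScaleCalibration(pixel_size_um=(2.0, 2.0), section_thickness_um=2.0)
        _, m1, _ = morpho.nucleus_volume(lab, c1)
        _, m2, _ = morpho.nucleus_volume(lab, c2)
        assert m2 == pytest.approx(8.0 * m1)


class TestVesselDiameter:
    def test_capillary_tube_measures_two_microns(self):
        tree = [ph.Branch(start_um=(2.0, 32 * 0.32, 32 * 0.32), direction=(1, 0, 0),
                          length_um=36.0, radius_um=1.0)]
        spec = ph.PhantomSpec(volume_shape_vox=(40, 64, 64), vessel_tree=tree, noise_sd=0.0)
        _, _, truth = ph.generate_phantom(spec)
        mask = vasc.VesselMask(truth.vessel_mask, voxel_size_um=spec.voxel_size_um)
        pt = tuple(int(v) for v in np.argwhere(truth.vessel_mask)[200])
        d, note = morpho.vessel_diameter(mask, pt)
        assert abs(d - 2.0) <= 0.32
        assert "centerline" in note

    def test_thick_tube_diameter_within_two_percent(self):
        tree = [ph.Branch(start_um=(32.0, 4.0, 60.0), direction=(0, 1, 0),
                          length_um=110.0, radius_um=25.0)]
        spec = ph.PhantomSpec(volume_shape_vox=(64, 120, 120), voxel_size_um=(1, 1, 1),
                              vessel_tree=tree, noise_sd=0.0)
        _, _, truth = ph.generate_phantom(spec)
        mask = vasc.VesselMask(truth.vessel_mask, voxel_size_um=(1, 1, 1))
        fg = np.argwhere(truth.vessel_mask)
        pt = tuple(int(v) for v in fg[len(fg) // 2])
        d, _ = morpho.vessel_diameter(mask, pt)
        assert abs(d - 50.0) / 50.0 < 0.02

    def test_one_voxel_line_measures_two_voxel_extents(self):
        # an isolated 1-voxel line has EDT of one in-plane voxel at its
        # center, so twice the transform spans two voxel extents
        line = np.zeros((5, 9, 9), dtype=bool)
        line[2, 4, 1:8] = True
        mask = vasc.VesselMask(line, voxel_size_um=(1.0, 0.32, 0.32))
        d, _ = morpho.vessel_diameter(mask, (2, 4, 4))
        assert d == pytest.approx(0.64)

    def test_point_outside_mask_rejected(self):
        mask = vasc.VesselMask(np.zeros((3, 3, 3), dtype=bool))
        with pytest.raises(ValueError, match="outside"):
            morpho.vessel_diameter(mask, (0, 0, 0))


def test_records_csv_roundtrip(tmp_path):
    rec = morpho.MorphometryRecord(
        feature_id="n1", feature_type="nucleus_volume", value=99.4, units="um^3",
        location_vox=(1, 2, 3), method="voxel count",
    )
    path = tmp_path / "m.csv"
    morpho.append_records_csv(path, [rec])
    morpho.append_records_csv(path, [rec])
    import pandas as pd

    table = pd.read_csv(path)
    assert len(table) == 2
    assert table.loc[0, "type"] == "nucleus_volume"
    with pytest.raises(ValueError, match="feature type"):
        morpho.MorphometryRecord("x", "nonsense", 1.0, "um", (), "")
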