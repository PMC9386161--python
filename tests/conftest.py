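"""Shared fixtures: small phantoms and analytic meshes.

Everything is generated at test time from fixed seeds; module scope keeps
the larger phantoms to one generation per session part.
"""

import numpy as np
import pytest
import trimesh
from skimage.measure import marching_cubes

from cardiomost import phantom as ph
from cardiomost import vasc

FOREGROUND = 20000
BACKGROUND = 1000
DYNAMIC_RANGE = FOREGROUND - BACKGROUND


def sdf_mesh(f, lo, hi, n):
    """Triangulate the zero level set of an implicit function sampled on a
    regular grid — analytic test surfaces for the curvature operators."""
    ax = [np.linspace(l, h, n) for l, h in zip(lo, hi)]
    grids = np.meshgrid(*ax, indexing="ij")
    spacing = [(h - l) / (n - 1) for l, h in zip(lo, hi)]
    verts, faces, _, _ = marching_cubes(f(*grids), level=0.0, spacing=spacing)
    tm = trimesh.Trimesh(verts + np.asarray(lo), faces, process=True, validate=True)
    return vasc.SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


@pytest.fixture(scope="session")
def vessel_phantom():
    """Isotropic 1-um phantom of a radius-8 trunk with five radius-3 side
    branches, 5% noise — the vascular recovery scenario."""
    spec = ph.PhantomSpec(
        volume_shape_vox=(64, 160, 128),
        voxel_size_um=(1.0, 1.0, 1.0),
        vessel_tree=ph.five_branch_tree(),
        noise_sd=0.05 * DYNAMIC_RANGE,
        seed=7,
    )
    return spec, ph.generate_phantom(spec)


@pytest.fixture(scope="session")
def vessel_phantom_clean():
    """Noise-free variant of the five-branch tree phantom."""
    spec = ph.PhantomSpec(
        volume_shape_vox=(64, 160, 128),
        voxel_size_um=(1.0, 1.0, 1.0),
        vessel_tree=ph.five_branch_tree(),
        noise_sd=0.0,
        seed=1,
    )
    return spec, ph.generate_phantom(spec)


@pytest.fixture(scope="session")
def myocardium_sections():
    """Noise-free myocardium phantom shaped for 3 strips of 660 px with a
    20-px designed overlap per section."""
    spec = ph.PhantomSpec(volume_shape_vox=(4, 256, 1940), noise_sd=0.0, seed=2)
    myo, _, truth = ph.generate_phantom(spec)
    return spec, myo, truth


@pytest.fixture(scope="session")
def sphere_mesh():
    return sdf_mesh(
        lambda z, y, x: np.sqrt(z**2 + y**2 + x**2) - 10.0, (-13,) * 3, (13,) * 3, 53
    )


@pytest.fixture(scope="session")
def cylinder_mesh():
    def cyl(z, y, x):
        return np.maximum(np.sqrt(y**2 + x**2) - 5.0, np.abs(z) - 30.0)

    return sdf_mesh(cyl, (-35, -8, -8), (35, 8, 8), 71)


@pytest.fixture(scope="session")
def box_mesh():
    def box(z, y, x):
        return np.maximum.reduce([np.abs(z) - 10, np.abs(y) - 10, np.abs(x) - 10])

    return sdf_mesh(box, (-13,) * 3, (13,) * 3, 53)
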