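"""Scale-calibrated morphometry.

Mirrors the ImageJ-style measurement workflow on serial-section data:
a scale calibration converts pixel indices to physical um, distances are
measured between picked points, nucleus cross-sections are fit with the
equal-second-moment ellipse ("Fit Ellipse" convention), nucleus volumes
are voxel counts times voxel volume, and vessel diameters come from the
Euclidean distance transform read at the centerline.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .vasc import VesselMask, fill_lumens

__all__ = [
    "ScaleCalibration",
    "MorphometryRecord",
    "measure_distance",
    "fit_nucleus_ellipse",
    "nucleus_volume",
    "vessel_diameter",
    "append_records_csv",
]

FEATURE_TYPES = (
    "distance",
    "nucleus_major_axis",
    "nucleus_minor_axis",
    "nucleus_volume",
    "vessel_diameter",
)


@dataclass
class ScaleCalibration:
    """Physical size of one pixel/section: in-plane (row, col) um and the
    section thickness um."""

    pixel_size_um: tuple[float, float] = (0.32, 0.32)
    section_thickness_um: float = 1.0

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.pixel_size_um) or self.section_thickness_um <= 0:
            raise ValueError("calibration sizes must be positive")

    @property
    def voxel_size_um(self) -> tuple[float, float, float]:
        return (self.section_thickness_um, *self.pixel_size_um)

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))


@dataclass
class MorphometryRecord:
    """One calibrated measurement, in um (lengths) or um^3 (volumes)."""

    feature_id: str
    feature_type: str
    value: float
    units: str
    location_vox: tuple
    method: str

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")


def measure_distance(p_start, p_end, cal: ScaleCalibration, image=None) -> float:
    """Euclidean point-to-point distance in um with anisotropic pixel
    scaling; ``image`` (optional) bounds-checks the picked points."""
    p0 = np.asarray(p_start, dtype=float)
    p1 = np.asarray(p_end, dtype=float)
    if image is not None:
        shape = np.asarray(np.asarray(image).shape)
        for p in (p0, p1):
            if np.any(p < 0) or np.any(p >= shape):
                raise ValueError(f"point {tuple(p)} outside image of shape {tuple(shape)}")
    scale = np.asarray(cal.pixel_size_um, dtype=float)
    d = float(np.linalg.norm((p1 - p0) * scale))
    if d == 0.0:
        warnings.warn("start and end points coincide; distance is 0")
    return d


def fit_nucleus_ellipse(mask2d: np.ndarray, cal: ScaleCalibration):
    """Equal-second-moment ellipse of a 2D region.

    Pixel centers are scaled to um (anisotropic), the central second
    moments get the per-pixel continuous-coverage term (p^2/12) added,
    and the ellipse with the same normalized second moments is returned
    as ``(major_um, minor_um, orientation_deg)``.  Orientation is the
    angle of the major axis against the column (x) axis, in (-90, 90].
    Regions under 5 pixels are rejected as unreliable.
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    coords = np.argwhere(mask2d)
    if coords.shape[0] < 5:
        raise ValueError(f"region has {coords.shape[0]} pixels; need at least 5 for an ellipse fit")
    py, px = cal.pixel_size_um
    pts = coords * np.array([py, px])
    pts = pts - pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    cov += np.diag([py**2 / 12.0, px**2 / 12.0])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    minor = 4.0 * np.sqrt(max(evals[0], 0.0))
    major = 4.0 * np.sqrt(max(evals[1], 0.0))
    vy, vx = evecs[:, 1]
    orientation = np.degrees(np.arctan2(vy, vx))
    if orientation <= -90.0:
        orientation += 180.0
    elif orientation > 90.0:
        orientation -= 180.0
    return float(major), float(minor), float(orientation)


def nucleus_volume(label3d: np.ndarray, cal: ScaleCalibration):
    """Per-label voxel volumes and the cohort summary.

    Returns ``(volumes, mean, sd)`` where ``volumes`` maps label to
    um^3 (voxel count x voxel volume); the summary is the unweighted mean
    and sample (n-1) standard deviation across labels.  Empty labels in
    the range 1..max are skipped with a warning.
    """
    label3d = np.asarray(label3d)
    labels, counts = np.unique(label3d[label3d > 0], return_counts=True)
    if labels.size == 0:
        raise ValueError("no labeled voxels")
    present = set(int(l) for l in labels)
    missing = sorted(set(range(1, int(labels.max()) + 1)) - present)
    if missing:
        warnings.warn(f"labels with no voxels skipped: {missing}")
    vv = cal.voxel_volume_um3
    volumes = {int(l): float(c) * vv for l, c in zip(labels, counts)}
    vals = np.array(list(volumes.values()))
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return volumes, mean, sd


def vessel_diameter(mask: VesselMask, point_on_vessel) -> tuple[float, str]:
    """Local vessel diameter at the centerline nearest a picked point.

    The lumen-filled mask's anisotropic Euclidean distance transform is
    read at the skeleton voxel nearest ``point_on_vessel``; twice that
    value is the diameter in um.  Returns ``(diameter_um, method_note)``
    where the note records the centerline voxel used.
    """
    point = tuple(int(p) for p in point_on_vessel)
    m = mask.mask
    if not m[point]:
        raise ValueError(f"point {point} is outside the vessel mask")
    vs = np.asarray(mask.voxel_size_um, dtype=float)
    filled = fill_lumens(m)
    from skimage.morphology import skeletonize

    skel = skeletonize(filled)
    coords = np.argwhere(skel)
    if coords.shape[0] == 0:
        raise ValueError("mask has no skeleton (degenerate structure)")
    edt = ndimage.distance_transform_edt(filled, sampling=vs)
    d = np.linalg.norm((coords - np.asarray(point)) * vs, axis=1)
    cl = coords[int(np.argmin(d))]
    diameter = float(2.0 * edt[tuple(cl)])
    note = f"2x EDT at centerline voxel {tuple(int(c) for c in cl)}"
    return diameter, note


def append_records_csv(path, records) -> None:
    """Append measurement records to a CSV with the standard columns
    (feature_id, type, value, units, z, y, x, method)."""
    path = Path(path)
    new = not path.exists()
    with path.open("a", newline="") as fh:
        w = csv.writer(fh)
        if new:
            w.writerow(["feature_id", "type", "value", "units", "z", "y", "x", "method"])
        for r in records:
            loc = tuple(r.location_vox) + (None,) * (3 - len(r.location_vox))
            w.writerow([r.feature_id, r.feature_type, r.value, r.units, *loc[:3], r.method])
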