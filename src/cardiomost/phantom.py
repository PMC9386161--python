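"""Synthetic dual-channel heart phantom with exact ground truth.

Block-face serial-section microscopes image a resin-embedded heart as
overlapping line-scan strips, two fluorescence channels at a time: a
myocardium counterstain (bright cylindrical cardiomyocytes with brighter
elliptical nuclei and dark intercalated-disc gaps) and a vascular
endothelium reporter (bright vessel walls down to ~2 um capillaries).
This module builds volumes with that structure from first principles so
that stitching, pyramid storage, rendering, segmentation and morphometry
can all be exercised against a known answer.

Conventions
-----------
Arrays are indexed ``(z, y, x)`` = (section, row, column); voxel centers
sit at integer indices and the physical position of voxel ``i`` along an
axis is ``i * voxel_size_um`` for that axis.  All shape and voxel-size
triples in this package follow the same ``(z, y, x)`` order.  The default
sampling of (1.0, 0.32, 0.32) um matches 0.32 x 0.32 um in-plane pixels
with 1-um sections.

The transmural (wall-depth) direction is the row axis: the wall is split
into three layers (epi / mid / endo) whose muscle fibers run along z,
along x, and along z again — mimicking the vertical / circumferential /
vertical arrangement of ventricular myocardium.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .mosaic import StripImage

__all__ = [
    "Branch",
    "PhantomSpec",
    "GroundTruth",
    "InvalidSpecError",
    "generate_phantom",
    "emit_strips",
    "write_phantom",
    "default_vessel_tree",
    "five_branch_tree",
]

DTYPE = np.uint16
DTYPE_MAX = np.iinfo(DTYPE).max

# a vessel whose radius exceeds this many in-plane voxels renders as a
# hollow wall (lumen at background); smaller vessels render filled
HOLLOW_RADIUS_VOX = 3.0


class InvalidSpecError(ValueError):
    """Raised when a phantom specification violates its invariants."""


@dataclass
class Branch:
    """One straight vessel segment of the phantom tree.

    ``start_um`` is the (z, y, x) position of the proximal end in um,
    ``direction`` is normalized at construction, children may start
    anywhere (typically at points along the parent).
    """

    start_um: tuple[float, float, float]
    direction: tuple[float, float, float]
    length_um: float
    radius_um: float
    children: list["Branch"] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if n == 0:
            raise InvalidSpecError("branch direction must be nonzero")
        self.direction = tuple(d / n)
        if self.length_um <= 0 or self.radius_um <= 0:
            raise InvalidSpecError("branch length and radius must be positive")

    @property
    def end_um(self) -> tuple[float, float, float]:
        return tuple(
            np.asarray(self.start_um) + self.length_um * np.asarray(self.direction)
        )

    def walk(self):
        """Yield this branch and all descendants depth-first."""
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class PhantomSpec:
    """Parameters of the synthetic heart volume.

    All lengths are um.  ``volume_shape_vox`` and ``voxel_size_um`` are in
    (z, y, x) array order.  ``layer_boundaries_frac`` splits the row axis
    (transmural depth) into epi / mid / endo layers.
    """

    volume_shape_vox: tuple[int, int, int]
    voxel_size_um: tuple[float, float, float] = (1.0, 0.32, 0.32)
    myocyte_radius_um: float = 6.0
    myocyte_gap_um: float = 0.64
    nucleus_axes_um: tuple[float, float, float] = (15.5, 3.5, 3.5)
    disc_spacing_um: float = 100.0
    layer_boundaries_frac: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    vessel_tree: list[Branch] = field(default_factory=list)
    capillary_radius_um: float = 1.0
    wall_thickness_um: float = 0.64
    background_level: int = 1000
    foreground_level: int = 20000
    nucleus_level: int = 30000
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        shape = tuple(int(s) for s in self.volume_shape_vox)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise InvalidSpecError(f"volume_shape_vox must be 3 positive ints, got {self.volume_shape_vox}")
        if any(v <= 0 for v in self.voxel_size_um):
            raise InvalidSpecError("voxel sizes must be positive")
        a, b, c = self.nucleus_axes_um
        if not (a >= b >= 0 and a >= c >= 0 and b > 0 and c > 0):
            raise InvalidSpecError("nucleus major axis must be >= minor axes, all positive")
        if self.myocyte_radius_um <= 0 or self.capillary_radius_um <= 0:
            raise InvalidSpecError("all radii must be positive")
        lo, hi = self.layer_boundaries_frac
        if not (0.0 < lo < hi < 1.0):
            raise InvalidSpecError("layer boundaries must be strictly increasing in (0, 1)")
        if self.disc_spacing_um <= 0:
            raise InvalidSpecError("disc spacing must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be nonnegative")


@dataclass
class GroundTruth:
    """Exact answers for every structure the phantom contains.

    ``nucleus_table`` has one row per nucleus label with its true axes,
    analytic ellipsoid volume and voxel-counted volume.  ``strip_offsets``
    maps (channel, section) to the true (row, col) origin of each strip
    and is filled in by :func:`emit_strips`.
    """

    myocyte_label_volume: np.ndarray
    nucleus_label_volume: np.ndarray
    nucleus_table: pd.DataFrame
    vessel_mask: np.ndarray
    vessel_centerline_graph: nx.Graph
    n_vessel_branches: int
    strip_offsets: dict = field(default_factory=dict)

    @property
    def branch_count(self) -> int:
        """Side-branch count: every branch except the root trunk."""
        return max(0, self.n_vessel_branches - 1)


# --------------------------------------------------------------------------
# generation

_LAYER_FIBER_AXES = (0, 2, 0)  # epi: along z, mid: along x, endo: along z


def _layer_row_ranges(n_rows: int, fracs: tuple[float, float]):
    b0 = int(round(fracs[0] * n_rows))
    b1 = int(round(fracs[1] * n_rows))
    return [(0, b0), (b0, b1), (b1, n_rows)]


def generate_phantom(spec: PhantomSpec):
    """Build both channels and the ground truth for ``spec``.

    Returns ``(channel_myo, channel_vasc, truth)``.  Identical spec and
    seed give bit-identical volumes: all randomness flows through one
    ``numpy`` generator seeded from ``spec.seed`` and the construction
    order is fixed.
    """
    spec.validate()
    shape = tuple(int(s) for s in spec.volume_shape_vox)
    vs = np.asarray(spec.voxel_size_um, dtype=float)
    rng = np.random.default_rng(spec.seed)

    myo = np.full(shape, float(spec.background_level), dtype=np.float32)
    myocyte_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)

    coords_um = [np.arange(n, dtype=float) * v for n, v in zip(shape, vs)]
    pitch = 2.0 * spec.myocyte_radius_um + spec.myocyte_gap_um
    r2 = spec.myocyte_radius_um**2

    nucleus_rows = []
    next_myocyte = 1
    next_nucleus = 1
    layer_ranges = _layer_row_ranges(shape[1], spec.layer_boundaries_frac)

    for layer, (row0, row1) in enumerate(layer_ranges):
        if row1 <= row0:
            continue
        fiber_axis = _LAYER_FIBER_AXES[layer]
        cross_axes = tuple(a for a in range(3) if a != fiber_axis)
        cu = coords_um[cross_axes[0]]
        cv = coords_um[cross_axes[1]]
        if cross_axes[0] == 1:
            cu = cu[row0:row1]
        if cross_axes[1] == 1:
            cv = cv[row0:row1]
        iu = np.floor(cu / pitch).astype(np.int64)
        iv = np.floor(cv / pitch).astype(np.int64)
        ru = cu - (iu + 0.5) * pitch
        rv = cv - (iv + 0.5) * pitch
        inside = (ru[:, None] ** 2 + rv[None, :] ** 2) <= r2
        n_iv = int(iv.max()) + 1 if iv.size else 0
        plane_labels = np.where(inside, next_myocyte + iu[:, None] * n_iv + iv[None, :], 0)

        # broadcast the cross-plane label pattern along the fiber axis,
        # restricted to this layer's rows
        sl = [slice(None)] * 3
        sl[1] = slice(row0, row1)
        sl = tuple(sl)
        expand = [None, None, None]
        expand[cross_axes[0]] = slice(None)
        expand[cross_axes[1]] = slice(None)
        block = plane_labels[tuple(x if x is not None else None for x in expand)]
        # np.broadcast_to over the fiber axis
        target_shape = [shape[0], row1 - row0, shape[2]]
        block3 = np.broadcast_to(block, tuple(target_shape))
        myocyte_labels[sl] = block3

        used = np.unique(plane_labels)
        used = used[used > 0]
        body = myocyte_labels[sl] > 0
        myo[sl][body] = spec.foreground_level

        # intercalated discs: 1-voxel-thick dark planes transverse to the
        # fiber axis, every disc_spacing_um, phase-shifted by half a spacing
        # so a disc never coincides with the volume boundary
        w = coords_um[fiber_axis]
        h = vs[fiber_axis]
        wp = w - spec.disc_spacing_um / 2.0
        near = np.abs(wp - np.round(wp / spec.disc_spacing_um) * spec.disc_spacing_um) <= h / 2.0
        disc_sel = [None, None, None]
        disc_sel[fiber_axis] = slice(None)
        disc_plane = near[tuple(x if x is not None else None for x in disc_sel)]
        # restrict to layer rows along axis 1 when fiber axis is not 1
        disc3 = np.broadcast_to(disc_plane, tuple(target_shape))
        region = myo[sl]
        region[disc3 & body] = spec.background_level
        myo[sl] = region

        # nuclei: one per myocyte per disc interval, centered, major axis
        # along the fiber
        major, minor_b, minor_c = spec.nucleus_axes_um
        semi = np.empty(3)
        semi[fiber_axis] = major / 2.0
        semi[cross_axes[0]] = minor_b / 2.0
        semi[cross_axes[1]] = minor_c / 2.0
        fiber_len = coords_um[fiber_axis][-1] if shape[fiber_axis] > 1 else 0.0
        disc_pos = [
            (k + 0.5) * spec.disc_spacing_um
            for k in range(int(np.floor(fiber_len / spec.disc_spacing_um - 0.5)) + 1)
            if 0.0 < (k + 0.5) * spec.disc_spacing_um < fiber_len
        ]
        bounds = [0.0, *disc_pos, fiber_len]
        if spec.nucleus_axes_um[1] / 2.0 >= spec.myocyte_radius_um:
            warnings.warn("nucleus minor axis exceeds myocyte radius; nuclei omitted")
            used = used[:0]
        extent_um = (np.asarray(shape) - 1) * vs
        for lab in used:
            k = int(lab - next_myocyte)
            ku, kv = divmod(k, n_iv) if n_iv else (0, 0)
            center = np.empty(3)
            center[cross_axes[0]] = (ku + 0.5) * pitch
            center[cross_axes[1]] = (kv + 0.5) * pitch
            # the nucleus must stay inside its own myocyte: cylinders whose
            # centers sit too close to a layer boundary or the volume edge
            # get no nucleus (their bodies are clipped there)
            contained = True
            for a in cross_axes:
                lo_b = row0 * vs[1] if a == 1 else 0.0
                hi_b = (row1 - 1) * vs[1] if a == 1 else extent_um[a]
                if center[a] - semi[a] < lo_b + vs[a] or center[a] + semi[a] > hi_b - vs[a]:
                    contained = False
            if not contained:
                continue
            for lo, hi in zip(bounds, bounds[1:]):
                if hi - lo < major:  # nucleus would not fit between discs
                    continue
                center[fiber_axis] = (lo + hi) / 2.0
                count = _rasterize_ellipsoid(
                    myo, nucleus_labels, center, semi, vs, next_nucleus, spec.nucleus_level
                )
                if count == 0:
                    continue
                nucleus_rows.append(
                    {
                        "label": next_nucleus,
                        "myocyte_label": int(lab),
                        "z_um": center[0],
                        "y_um": center[1],
                        "x_um": center[2],
                        "major_axis_um": major,
                        "minor_axis_b_um": minor_b,
                        "minor_axis_c_um": minor_c,
                        "analytic_volume_um3": 4.0 / 3.0 * np.pi * semi.prod(),
                        "voxel_count": count,
                        "voxel_volume_um3": count * float(vs.prod()),
                    }
                )
                next_nucleus += 1
        if used.size:
            next_myocyte = int(used.max()) + 1

    # ---- vascular channel ------------------------------------------------
    vasc = np.full(shape, float(spec.background_level), dtype=np.float32)
    vessel_mask = np.zeros(shape, dtype=bool)
    graph = nx.Graph()
    n_branches = 0
    in_plane = float(min(vs[1], vs[2]))
    for root in spec.vessel_tree:
        for br in root.walk():
            n_branches += 1
            _rasterize_branch(vasc, vessel_mask, br, spec, vs, in_plane)
            graph.add_edge(
                tuple(np.round(br.start_um, 6)),
                tuple(np.round(br.end_um, 6)),
                radius_um=br.radius_um,
                length_um=br.length_um,
            )
    graph.graph["n_branches"] = n_branches

    if spec.noise_sd > 0:
        myo += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
        vasc += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    channel_myo = np.clip(np.rint(myo), 0, DTYPE_MAX).astype(DTYPE)
    channel_vasc = np.clip(np.rint(vasc), 0, DTYPE_MAX).astype(DTYPE)

    table = pd.DataFrame(
        nucleus_rows,
        columns=[
            "label",
            "myocyte_label",
            "z_um",
            "y_um",
            "x_um",
            "major_axis_um",
            "minor_axis_b_um",
            "minor_axis_c_um",
            "analytic_volume_um3",
            "voxel_count",
            "voxel_volume_um3",
        ],
    )
    truth = GroundTruth(
        myocyte_label_volume=myocyte_labels,
        nucleus_label_volume=nucleus_labels,
        nucleus_table=table,
        vessel_mask=vessel_mask,
        vessel_centerline_graph=graph,
        n_vessel_branches=n_branches,
    )
    return channel_myo, channel_vasc, truth


def _rasterize_ellipsoid(intensity, labels, center_um, semi_um, vs, label, level):
    """Paint an axis-aligned ellipsoid; returns the voxel count."""
    lo = np.maximum(np.floor((center_um - semi_um) / vs).astype(int) - 1, 0)
    hi = np.minimum(
        np.ceil((center_um + semi_um) / vs).astype(int) + 2, intensity.shape
    )
    if np.any(hi <= lo):
        return 0
    grids = np.meshgrid(
        *[np.arange(l, h) * v for l, h, v in zip(lo, hi, vs)], indexing="ij"
    )
    q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center_um, semi_um))
    inside = q <= 1.0
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    intensity[sl][inside] = level
    labels[sl][inside] = label
    return int(inside.sum())


def _rasterize_branch(vasc, mask, br: Branch, spec: PhantomSpec, vs, in_plane):
    """Paint one vessel segment: filled below the hollow threshold,
    a bright wall with dark lumen above it, plus elongated bright nucleus
    streaks on capillary walls."""
    p0 = np.asarray(br.start_um, dtype=float)
    p1 = np.asarray(br.end_um, dtype=float)
    r = br.radius_um
    margin = r + spec.wall_thickness_um + 2.0 * float(vs.max())
    lo_um = np.minimum(p0, p1) - margin
    hi_um = np.maximum(p0, p1) + margin
    extent_um = (np.asarray(vasc.shape) - 1) * vs
    if np.any(hi_um < 0) or np.any(lo_um > extent_um):
        warnings.warn(f"vessel branch at {br.start_um} lies outside the volume; skipped")
        return
    if np.any(p0 < -1e-9) or np.any(p0 > extent_um + 1e-9) or np.any(
        p1 < -1e-9
    ) or np.any(p1 > extent_um + 1e-9):
        warnings.warn(f"vessel branch at {br.start_um} exits the volume; clipped")
    lo = np.maximum(np.floor(lo_um / vs).astype(int), 0)
    hi = np.minimum(np.ceil(hi_um / vs).astype(int) + 1, vasc.shape)
    if np.any(hi <= lo):
        return
    grids = np.meshgrid(
        *[np.arange(l, h) * v for l, h, v in zip(lo, hi, vs)], indexing="ij"
    )
    p = np.stack(grids, axis=-1)
    d = p1 - p0
    L = float(np.linalg.norm(d))
    u = d / L
    rel = p - p0
    s = rel @ u  # arc-length coordinate along the centerline
    s_cl = np.clip(s, 0.0, L)
    dist = np.linalg.norm(rel - s_cl[..., None] * u, axis=-1)
    # soften the ends: distance to the capped segment, not the infinite line
    end_excess = np.maximum(np.maximum(-s, s - L), 0.0)
    dist = np.sqrt(dist**2 + end_excess**2)

    hollow = (r / in_plane) > HOLLOW_RADIUS_VOX
    if hollow:
        # the wall must span at least ~2 voxels or rasterization fragments it
        wall = max(spec.wall_thickness_um, 2.0 * float(vs.max()))
        bright = (dist <= r) & (dist >= r - wall)
    else:
        bright = dist <= r

    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    vasc[sl][bright] = spec.foreground_level
    mask[sl][bright] = True

    # endothelial nucleus streaks on capillary walls: short, brighter
    # stretches of the outer shell every ~20 um
    if r <= 1.5 * spec.capillary_radius_um:
        streak_len = 8.0
        streak_gap = 20.0
        phase = np.mod(s_cl, streak_gap)
        on_streak = (phase < streak_len) & (s > 0) & (s < L)
        shell = dist <= r
        streak = on_streak & shell & (dist >= max(r - in_plane, 0.0))
        region = vasc[sl]
        region[streak] = spec.nucleus_level
        vasc[sl] = region


def five_branch_tree(
    trunk_radius_um: float = 8.0,
    branch_radius_um: float = 3.0,
    center_zx_um: tuple[float, float] = (32.0, 64.0),
    trunk_start_y_um: float = 8.0,
    trunk_length_um: float = 144.0,
    branch_length_um: float = 45.0,
) -> list[Branch]:
    """A trunk with five alternating side branches, the topology of a
    coronary trunk traced from the aorta toward the apex.

    Junctions keep at least four trunk radii of clearance from the trunk
    ends: skeletonization retracts tube ends by about one radius, and the
    spur pruning rule removes endpoint paths shorter than three local
    radii, so branch counting is only well-posed with that clearance.
    """
    cz, cx = center_zx_um
    children = []
    for i in range(5):
        t = trunk_start_y_um + 36.0 + i * 16.0
        side = 1 if i % 2 == 0 else -1
        children.append(
            Branch(
                start_um=(cz, t, cx),
                direction=(0.15 * side, 0.25, 0.95 * side),
                length_um=branch_length_um,
                radius_um=branch_radius_um,
            )
        )
    return [
        Branch(
            start_um=(cz, trunk_start_y_um, cx),
            direction=(0.0, 1.0, 0.0),
            length_um=trunk_length_um,
            radius_um=trunk_radius_um,
            children=children,
        )
    ]


def default_vessel_tree(shape_vox, voxel_size_um=(1.0, 0.32, 0.32)):
    """A small trunk-plus-side-branches tree spanning the volume: one
    trunk along y (base to apex) with side branches angling into x/z,
    down to capillary-scale radii."""
    vs = np.asarray(voxel_size_um, dtype=float)
    extent = (np.asarray(shape_vox) - 1) * vs
    cz, cx = extent[0] / 2.0, extent[2] / 2.0
    trunk_len = extent[1] * 0.9
    trunk_r = min(8.0 * min(vs[1], vs[2]), extent[2] / 6.0)
    children = []
    for i in range(5):
        t = (i + 1) / 6.0 * trunk_len
        side = 1 if i % 2 == 0 else -1
        children.append(
            Branch(
                start_um=(cz, t, cx),
                direction=(0.0, 0.3, 0.95 * side),
                length_um=min(extent[2] / 2.5, 60.0),
                radius_um=3.0 * min(vs[1], vs[2]),
            )
        )
    trunk = Branch(
        start_um=(cz, extent[1] * 0.05, cx),
        direction=(0.0, 1.0, 0.0),
        length_um=trunk_len,
        radius_um=trunk_r,
        children=children,
    )
    return [trunk]


# --------------------------------------------------------------------------
# strip emission

def emit_strips(
    volume: np.ndarray,
    strip_width_px: int,
    overlap_px: int,
    *,
    channel: str = "myocardium",
    pixel_size_um: tuple[float, float] = (0.32, 0.32),
    truth: GroundTruth | None = None,
) -> list[list[StripImage]]:
    """Split each section of ``volume`` into overlapping line-scan strips.

    Strips of width ``strip_width_px`` share ``overlap_px`` columns with
    their right neighbor; the last strip is narrowed to end at the section
    edge.  Alternate strips are flagged with a reversed scan direction
    (metadata only — pixel order is normalized, mimicking the back-and-
    forth line scan of the acquisition).  True (row, col) origins are
    recorded in ``truth.strip_offsets`` when a ground-truth object is
    passed.  Returns one list of :class:`StripImage` per section.
    """
    if overlap_px < 0 or strip_width_px <= overlap_px:
        raise ValueError("need strip_width_px > overlap_px >= 0")
    volume = np.asarray(volume)
    nz, _, ncols = volume.shape
    if strip_width_px >= ncols:
        if strip_width_px > ncols:
            warnings.warn("strip wider than section; emitting a single strip")
        starts = [0]
        widths = [ncols]
    else:
        stride = strip_width_px - overlap_px
        starts = list(range(0, ncols - strip_width_px, stride))
        starts.append(ncols - strip_width_px)
        # drop a duplicate if the last regular start already lands flush
        starts = sorted(set(starts))
        widths = [strip_width_px] * len(starts)
    # the final strip is anchored at the section edge, so its overlap with
    # its left neighbor can exceed the nominal; each strip records the
    # actual designed overlap with its right neighbor
    pair_overlaps = [
        starts[i] + widths[i] - starts[i + 1] for i in range(len(starts) - 1)
    ] + [overlap_px]
    sections = []
    for z in range(nz):
        strips = []
        for i, (c0, w) in enumerate(zip(starts, widths)):
            strips.append(
                StripImage(
                    pixels=volume[z, :, c0 : c0 + w].copy(),
                    channel=channel,
                    section_index=z,
                    strip_index=i,
                    nominal_overlap_px=pair_overlaps[i],
                    pixel_size_um=tuple(pixel_size_um),
                    scan_reversed=bool(i % 2),
                )
            )
        if truth is not None:
            truth.strip_offsets[(channel, z)] = [(0, c0) for c0 in starts]
        sections.append(strips)
    return sections


# --------------------------------------------------------------------------
# on-disk output

def write_phantom(
    out_dir,
    spec: PhantomSpec,
    *,
    strip_width_px: int | None = None,
    overlap_px: int = 20,
) -> Path:
    """Generate a phantom and write it out: per-section TIFFs per channel
    (``{channel}_{z:05d}.tif``), optional strip TIFFs with JSON sidecars,
    and the ground truth as a compressed label archive plus CSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    myo, vasc, truth = generate_phantom(spec)
    channels = {"myocardium": myo, "vasculature": vasc}
    for name, vol in channels.items():
        sec_dir = out / "sections"
        sec_dir.mkdir(exist_ok=True)
        for z in range(vol.shape[0]):
            tifffile.imwrite(sec_dir / f"{name}_{z:05d}.tif", vol[z])
    if strip_width_px is not None:
        strip_dir = out / "strips"
        strip_dir.mkdir(exist_ok=True)
        for name, vol in channels.items():
            per_sec = emit_strips(
                vol,
                strip_width_px,
                overlap_px,
                channel=name,
                pixel_size_um=(spec.voxel_size_um[1], spec.voxel_size_um[2]),
                truth=truth,
            )
            for strips in per_sec:
                for s in strips:
                    stem = f"{name}_z{s.section_index:05d}_s{s.strip_index:02d}"
                    tifffile.imwrite(strip_dir / f"{stem}.tif", s.pixels)
                    meta = {
                        "channel": s.channel,
                        "section_index": s.section_index,
                        "strip_index": s.strip_index,
                        "nominal_overlap_px": s.nominal_overlap_px,
                        "pixel_size_um": list(s.pixel_size_um),
                        "scan_reversed": s.scan_reversed,
                    }
                    (strip_dir / f"{stem}.json").write_text(json.dumps(meta, indent=1))
    np.savez_compressed(
        out / "ground_truth_labels.npz",
        myocyte_label_volume=truth.myocyte_label_volume,
        nucleus_label_volume=truth.nucleus_label_volume,
        vessel_mask=truth.vessel_mask,
    )
    truth.nucleus_table.to_csv(out / "ground_truth_nuclei.csv", index=False)
    offsets_rows = [
        {"channel": ch, "section": z, "strip": i, "d_row": r, "d_col": c}
        for (ch, z), offs in truth.strip_offsets.items()
        for i, (r, c) in enumerate(offs)
    ]
    pd.DataFrame(
        offsets_rows, columns=["channel", "section", "strip", "d_row", "d_col"]
    ).to_csv(out / "ground_truth_strip_offsets.csv", index=False)
    return out
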