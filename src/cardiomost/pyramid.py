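"""Chunked multilevel-resolution volume store.

Terabyte-scale serial-section volumes are kept as a pyramid of
progressively block-reduced copies so that whole-organ overviews and
full-resolution regions of interest can both be read cheaply.  Level 0
is the native voxel size; each coarser level divides the previous one by
a per-axis integer factor (default 2,2,2).  The store is a zarr group —
one chunked array per level, JSON metadata alongside — so levels can be
written lazily and read by region.

Mean reduction rounds half-to-even before the 16-bit cast, and partial
edge blocks average only the voxels they actually contain, so a constant
volume stays exactly constant at every level and the global mean drifts
by at most the rounding error per level.
"""

from __future__ import annotations

import numbers
from pathlib import Path

import numpy as np
import tifffile
import zarr
from scipy import ndimage

from .mosaic import SectionImage

__all__ = ["VolumePyramid", "build_pyramid", "block_reduce_exact", "ResampledVolume"]

DTYPE = np.uint16


def _block_starts(n: int, f: int) -> np.ndarray:
    return np.arange(0, n, f)


def block_reduce_exact(arr: np.ndarray, factors, method: str = "mean") -> np.ndarray:
    """Block-reduce ``arr`` by integer ``factors`` per axis.

    Partial blocks at the upper edges reduce over their actual voxels
    only (no padding bias).  ``mean`` accumulates in float64 and rounds
    half-to-even; ``max`` takes the block maximum.
    """
    factors = tuple(int(f) for f in factors)
    if any(f < 1 for f in factors):
        raise ValueError("reduction factors must be >= 1")
    if method == "max":
        out = arr
        for ax, f in enumerate(factors):
            if f > 1:
                out = np.maximum.reduceat(out, _block_starts(out.shape[ax], f), axis=ax)
        return out.astype(arr.dtype, copy=False)
    if method != "mean":
        raise ValueError(f"unknown reduction method {method!r}")
    sums = arr.astype(np.float64)
    counts = 1.0
    for ax, f in enumerate(factors):
        if f > 1:
            n = sums.shape[ax]
            starts = _block_starts(n, f)
            sums = np.add.reduceat(sums, starts, axis=ax)
            per_block = np.minimum(starts + f, n) - starts
            shape = [1] * sums.ndim
            shape[ax] = len(starts)
            counts = counts * per_block.reshape(shape)
    mean = sums / counts
    if np.issubdtype(arr.dtype, np.integer):
        return np.rint(mean).astype(arr.dtype)
    return mean.astype(arr.dtype)


class ResampledVolume:
    """A volume resampled onto a target grid; carries its effective voxel
    size so downstream measurements stay calibrated."""

    def __init__(self, data: np.ndarray, voxel_size_um):
        self.data = data
        self.voxel_size_um = tuple(float(v) for v in voxel_size_um)

    @property
    def shape(self):
        return self.data.shape


class VolumePyramid:
    """Multilevel chunked 3D store for one channel.

    Levels are zarr arrays ``level_0 .. level_{n-1}``; each carries its
    voxel size (um, z/y/x order) and shape in its attributes, group
    attributes record channel, reduction method and provenance.
    """

    def __init__(self, group: zarr.Group):
        self._group = group

    # -- construction ------------------------------------------------------

    @classmethod
    def open(cls, store_path) -> "VolumePyramid":
        return cls(zarr.open_group(str(store_path), mode="r"))

    @property
    def n_levels(self) -> int:
        return int(self._group.attrs["n_levels"])

    @property
    def channel(self) -> str:
        return self._group.attrs.get("channel", "")

    def level(self, l: int) -> zarr.Array:
        if not 0 <= l < self.n_levels:
            raise IndexError(f"level {l} out of range (0..{self.n_levels - 1})")
        return self._group[f"level_{l}"]

    def level_voxel_size(self, l: int):
        return tuple(self.level(l).attrs["voxel_size_um"])

    def level_shape(self, l: int):
        return tuple(self.level(l).shape)

    # -- access ------------------------------------------------------------

    def read_region(self, level: int, origin_vox, shape_vox) -> np.ndarray:
        """Exact stored voxels of a sub-box of one level.

        Zero-volume shapes return an empty array; out-of-bounds requests
        raise with a suggestion of the nearest valid (clipped) box.
        """
        arr = self.level(level)
        origin = tuple(int(o) for o in origin_vox)
        shape = tuple(int(s) for s in shape_vox)
        if any(s < 0 for s in shape):
            raise ValueError("region shape must be nonnegative")
        if any(s == 0 for s in shape):
            return np.empty(shape, dtype=arr.dtype)
        if any(o < 0 or o + s > n for o, s, n in zip(origin, shape, arr.shape)):
            clipped_origin = tuple(min(max(o, 0), n - 1) for o, n in zip(origin, arr.shape))
            clipped_shape = tuple(
                min(s, n - co) for s, n, co in zip(shape, arr.shape, clipped_origin)
            )
            raise ValueError(
                f"region origin={origin} shape={shape} exceeds level {level} "
                f"bounds {arr.shape}; nearest valid box is origin={clipped_origin} "
                f"shape={clipped_shape}"
            )
        sl = tuple(slice(o, o + s) for o, s in zip(origin, shape))
        return np.asarray(arr[sl])

    def read_full(self, level: int = 0) -> np.ndarray:
        return self.read_region(level, (0, 0, 0), self.level_shape(level))

    def resample_to_voxel(self, target_voxel_um) -> ResampledVolume:
        """Resample onto an arbitrary coarser grid (e.g. the 10-um display
        grid used for whole-organ overviews).

        Picks the coarsest stored level whose voxel size does not exceed
        the target on any axis, then trilinearly interpolates onto the
        target grid; the non-integer ratio between native and display
        sampling (10 / 0.32 = 31.25 in-plane) makes interpolation, not
        decimation, the right primitive.  Output voxel j sits at physical
        position j * target, matching the package's voxel-center
        convention; the output covers the full physical extent
        (ceil(extent / target) voxels per axis).
        """
        target = np.asarray(target_voxel_um, dtype=float)
        vs0 = np.asarray(self.level_voxel_size(0))
        if np.any(target < vs0 - 1e-9):
            raise ValueError(
                f"target voxel {tuple(target)} is finer than level 0 {tuple(vs0)}; "
                "upsampling is not supported"
            )
        best = 0
        for l in range(self.n_levels):
            if np.all(np.asarray(self.level_voxel_size(l)) <= target + 1e-9):
                best = l
        vs = np.asarray(self.level_voxel_size(best))
        src = self.read_full(best).astype(np.float32)
        extent = np.asarray(self.level_shape(0)) * vs0
        out_shape = tuple(int(np.ceil(e / t)) for e, t in zip(extent, target))
        axes = [np.arange(n) * t / v for n, t, v in zip(out_shape, target, vs)]
        grid = np.meshgrid(*axes, indexing="ij")
        data = ndimage.map_coordinates(src, np.stack(grid), order=1, mode="nearest")
        if np.issubdtype(self.level(best).dtype, np.integer):
            data = np.rint(data).astype(self.level(best).dtype)
        return ResampledVolume(data, tuple(target))

    # -- export ------------------------------------------------------------

    def export_tiff(self, path, level: int = 0) -> None:
        tifffile.imwrite(Path(path), self.read_full(level))


def _as_volume(sections) -> tuple[np.ndarray, str, tuple[float, float, float]]:
    if isinstance(sections, np.ndarray):
        if sections.ndim != 3:
            raise ValueError("expected a 3D volume")
        return sections, "", (1.0, 1.0, 1.0)
    imgs = list(sections)
    if not imgs:
        raise ValueError("no sections")
    first = imgs[0]
    if isinstance(first, SectionImage):
        shape0 = first.pixels.shape
        for s in imgs:
            if s.pixels.shape != shape0:
                raise ValueError(
                    f"section z={s.section_index} has shape {s.pixels.shape}, "
                    f"expected {shape0}"
                )
        z_order = [s.section_index for s in imgs]
        if any(b <= a for a, b in zip(z_order, z_order[1:])):
            raise ValueError("sections must be in strictly increasing z order")
        vol = np.stack([s.pixels for s in imgs])
        py, px = first.pixel_size_um
        return vol, first.channel, (1.0, py, px)
    vol = np.stack([np.asarray(s) for s in imgs])
    return vol, "", (1.0, 1.0, 1.0)


def build_pyramid(
    sections,
    store_path=None,
    chunk_shape_vox=(64, 64, 64),
    factors=(2, 2, 2),
    method: str = "mean",
    voxel_size_um=None,
    channel: str | None = None,
    n_levels: int | None = None,
    max_coarse_extent: int = 256,
) -> VolumePyramid:
    """Build a pyramid from stitched sections (or a raw (z, y, x) array).

    ``factors`` is one per-axis reduction triple applied at every level
    (or a list of triples, one per level step).  When ``n_levels`` is not
    given, levels are added until the coarsest fits ``max_coarse_extent``
    per axis.  Chunks are written level by level, z-chunk-row at a time,
    so peak memory stays near one chunk row per level.  ``store_path``
    ``None`` keeps the store in memory.
    """
    vol, auto_channel, auto_vs = _as_volume(sections)
    if voxel_size_um is None:
        voxel_size_um = auto_vs
    if channel is None:
        channel = auto_channel
    if method not in ("mean", "max"):
        raise ValueError(f"unknown reduction method {method!r}")
    if isinstance(factors[0], numbers.Number):
        per_level_factors = None
        base_factor = tuple(int(f) for f in factors)
    else:
        per_level_factors = [tuple(int(f) for f in fs) for fs in factors]
        base_factor = None

    shapes = [tuple(vol.shape)]
    voxel_sizes = [tuple(float(v) for v in voxel_size_um)]
    step_factors = []
    while True:
        if per_level_factors is not None:
            if len(step_factors) >= len(per_level_factors):
                break
            f = per_level_factors[len(step_factors)]
        else:
            if n_levels is not None:
                if len(shapes) >= n_levels:
                    break
            elif max(shapes[-1]) <= max_coarse_extent:
                break
            f = base_factor
        nxt = tuple(int(np.ceil(s / ff)) for s, ff in zip(shapes[-1], f))
        if nxt == shapes[-1]:
            break
        step_factors.append(f)
        shapes.append(nxt)
        voxel_sizes.append(tuple(v * ff for v, ff in zip(voxel_sizes[-1], f)))

    group = zarr.open_group(str(store_path) if store_path is not None else None, mode="w")
    group.attrs.update(
        {
            "n_levels": len(shapes),
            "channel": channel,
            "reduction_method": method,
            "provenance": "cardiomost.pyramid.build_pyramid",
        }
    )
    chunk = tuple(int(c) for c in chunk_shape_vox)
    arrays = []
    for l, (shp, vs) in enumerate(zip(shapes, voxel_sizes)):
        arr = group.create_array(
            f"level_{l}",
            shape=shp,
            chunks=tuple(min(c, s) for c, s in zip(chunk, shp)),
            dtype=DTYPE,
        )
        arr.attrs["voxel_size_um"] = list(vs)
        arr.attrs["reduction_method"] = "source" if l == 0 else method
        arrays.append(arr)

    # level 0: copy in z-chunk rows
    cz = arrays[0].chunks[0]
    for z0 in range(0, vol.shape[0], cz):
        arrays[0][z0 : z0 + cz] = np.ascontiguousarray(vol[z0 : z0 + cz]).astype(DTYPE)
    # coarser levels: reduce the previous level one output z-chunk-row at a time
    for l, f in enumerate(step_factors, start=1):
        src, dst = arrays[l - 1], arrays[l]
        cz = dst.chunks[0]
        for z0 in range(0, dst.shape[0], cz):
            z1 = min(z0 + cz, dst.shape[0])
            block = np.asarray(src[z0 * f[0] : min(z1 * f[0], src.shape[0])])
            dst[z0:z1] = block_reduce_exact(block, f, method=method)
    return VolumePyramid(group)
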