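"""Display products: slab maximum-intensity projections, two-channel
pseudocolor merges, and depth-coded projections.

The myocardium channel is typically shown one section (1 um) at a time to
keep single cells resolvable, while the vascular channel is projected
over slabs of hundreds of microns so the network's connectivity is
visible.  Depth coding binarizes each slice of a slab, assigns it a color
sampled at equal intervals along a color bar, and stacks the colored
slices so that the hue of each foreground pixel encodes its slice of
origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb
from skimage.filters import threshold_otsu

__all__ = [
    "ProjectionSpec",
    "DepthCodedImage",
    "AXIS_NAMES",
    "max_projection",
    "merge_channels",
    "depth_code",
    "depth_colormap",
]

# native stack axes: axial = across-z planes, the two resliced views map
# to the row and column axes
AXIS_NAMES = {"axial": 0, "sagittal": 1, "coronal": 2}

FUCHSIA = (255, 0, 255)
GREEN = (0, 255, 0)


@dataclass
class ProjectionSpec:
    """A slab to project: ``thickness_slices`` slices starting at
    ``start_index`` along the named anatomical axis."""

    axis: str = "axial"
    start_index: int = 0
    thickness_slices: int = 1
    channel: str = ""

    def validate(self, volume_shape) -> int:
        if self.axis not in AXIS_NAMES:
            raise ValueError(f"unknown axis {self.axis!r}; expected one of {sorted(AXIS_NAMES)}")
        ax = AXIS_NAMES[self.axis]
        n = volume_shape[ax]
        if self.thickness_slices < 1:
            raise ValueError("slab thickness must be at least 1 slice")
        if not (0 <= self.start_index and self.start_index + self.thickness_slices <= n):
            raise ValueError(
                f"slab [{self.start_index}, {self.start_index + self.thickness_slices}) "
                f"exceeds axis {self.axis!r} extent {n}"
            )
        return ax


@dataclass
class DepthCodedImage:
    """RGB projection whose color encodes slice of origin.

    ``slice_of_origin`` is -1 at background; every foreground pixel's rgb
    equals ``colormap[slice_of_origin]``.
    """

    rgb: np.ndarray
    colormap: np.ndarray
    slice_of_origin: np.ndarray
    threshold_used: float


def max_projection(volume: np.ndarray, spec: ProjectionSpec) -> np.ndarray:
    """Per-pixel maximum over the selected slab."""
    volume = np.asarray(volume)
    ax = spec.validate(volume.shape)
    sl = [slice(None)] * 3
    sl[ax] = slice(spec.start_index, spec.start_index + spec.thickness_slices)
    return volume[tuple(sl)].max(axis=ax)


def _window(img: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        raise ValueError("contrast window must have hi > lo")
    return np.clip((img.astype(np.float64) - lo) / (hi - lo), 0.0, 1.0)


def merge_channels(
    myo: np.ndarray,
    vasc: np.ndarray,
    myo_color=FUCHSIA,
    vasc_color=GREEN,
    myo_window=None,
    vasc_window=None,
) -> np.ndarray:
    """Merge the two channels into one 8-bit RGB image.

    Each channel is contrast-windowed to [0, 1] (default window: its own
    min..max), multiplied by its display color — fuchsia for myocardium,
    green for vasculature by convention — then summed per pixel and
    clipped, so coincident saturation of both channels renders white.
    """
    myo = np.asarray(myo)
    vasc = np.asarray(vasc)
    if myo.shape != vasc.shape:
        raise ValueError(f"channel shapes differ: {myo.shape} vs {vasc.shape}")
    if myo_window is None:
        myo_window = (float(myo.min()), float(max(myo.max(), myo.min() + 1)))
    if vasc_window is None:
        vasc_window = (float(vasc.min()), float(max(vasc.max(), vasc.min() + 1)))
    m = _window(myo, *myo_window)
    v = _window(vasc, *vasc_window)
    rgb = m[..., None] * np.asarray(myo_color, dtype=np.float64) + v[..., None] * np.asarray(
        vasc_color, dtype=np.float64
    )
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def depth_colormap(k: int, hue_start: float = 2.0 / 3.0, hue_end: float = 0.0) -> np.ndarray:
    """k colors at equal intervals along an HSV hue sweep (default
    blue -> red), as uint8 RGB rows."""
    if k < 1:
        raise ValueError("need at least one color")
    hues = np.linspace(hue_start, hue_end, k) if k > 1 else np.array([hue_start])
    hsv = np.stack([hues, np.ones(k), np.ones(k)], axis=-1)
    return np.rint(hsv_to_rgb(hsv) * 255).astype(np.uint8)


def depth_code(
    stack,
    threshold="auto",
    order: str = "last_hit",
    colormap: np.ndarray | None = None,
) -> DepthCodedImage:
    """Depth-code a stack of k slices.

    Each slice is binarized at ``threshold`` (``"auto"`` = Otsu on the
    whole-slab histogram); the color bar is linearized into k colors, one
    per slice in order; the colored slices are stacked sequentially.
    Where several slices are foreground at the same pixel, ``last_hit``
    keeps the deepest (later slices overwrite earlier), ``first_hit``
    keeps the shallowest.
    """
    slices = [np.asarray(s) for s in stack]
    if len(slices) == 0:
        raise ValueError("empty stack")
    shape0 = slices[0].shape
    if any(s.shape != shape0 for s in slices):
        raise ValueError("all slices must share one shape")
    if order not in ("first_hit", "last_hit"):
        raise ValueError(f"unknown order {order!r}")
    k = len(slices)
    cube = np.stack(slices)
    if threshold == "auto":
        thr = float(threshold_otsu(cube)) if np.ptp(cube) > 0 else float(cube.max())
    else:
        thr = float(threshold)
    fg = cube >= thr
    if not fg.any():
        warnings.warn("threshold above the data range: depth-coded image is all background")
    if colormap is None:
        colormap = depth_colormap(k)
    colormap = np.asarray(colormap, dtype=np.uint8)
    if colormap.shape != (k, 3):
        raise ValueError(f"colormap must be (k, 3) = ({k}, 3), got {colormap.shape}")

    any_fg = fg.any(axis=0)
    if order == "last_hit":
        winner = (k - 1) - np.argmax(fg[::-1], axis=0)
    else:
        winner = np.argmax(fg, axis=0)
    slice_of_origin = np.where(any_fg, winner, -1).astype(np.int32)
    rgb = np.zeros(shape0 + (3,), dtype=np.uint8)
    rgb[any_fg] = colormap[winner[any_fg]]
    return DepthCodedImage(
        rgb=rgb, colormap=colormap, slice_of_origin=slice_of_origin, threshold_used=thr
    )
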