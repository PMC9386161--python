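"""Strip-to-section stitching.

A line-scan microscope delivers each physical section as a row of narrow
strips whose edges overlap by a nominal number of columns.  Stitching is
two steps: estimate the true integer translation between each adjacent
pair by normalized cross-correlation over the overlap band, then place
the strips left-to-right and remove the duplicated columns (``cut``) or
blend across them (``feather``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "StripImage",
    "SectionImage",
    "StitchGapError",
    "estimate_offset",
    "stitch_section",
    "load_strips",
]

CHANNELS = ("myocardium", "vasculature")


class StitchGapError(ValueError):
    """Raised when computed offsets leave a gap between adjacent strips."""


@dataclass
class StripImage:
    """One line-scan strip of one section of one channel."""

    pixels: np.ndarray
    channel: str
    section_index: int
    strip_index: int
    nominal_overlap_px: int
    pixel_size_um: tuple[float, float] = (0.32, 0.32)
    scan_reversed: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("strip pixels must be a non-empty 2D array")
        if self.nominal_overlap_px >= self.pixels.shape[1]:
            raise ValueError("nominal overlap must be smaller than the strip width")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass
class SectionImage:
    """A stitched section; ``provenance`` maps each strip to the column
    range it contributed, and those ranges partition the width."""

    pixels: np.ndarray
    section_index: int
    channel: str
    pixel_size_um: tuple[float, float] = (0.32, 0.32)
    provenance: list[tuple[int, tuple[int, int]]] = field(default_factory=list)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    a -= a.mean()
    b -= b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def estimate_offset(
    strip_a: StripImage,
    strip_b: StripImage,
    search_radius_px: int = 10,
    row_search_px: int = 3,
    min_score: float = 0.2,
):
    """Estimate the (row, col) origin of ``strip_b`` relative to ``strip_a``.

    Exhaustive integer search within ``±search_radius_px`` columns of the
    nominal offset (strip width minus nominal overlap) and
    ``±row_search_px`` rows, scoring each candidate by the normalized
    cross-correlation of the implied overlap band.  Returns
    ``(d_row, d_col, score)`` with score in [-1, 1].  A flat (zero
    variance) overlap band cannot be registered: the nominal offset is
    returned with score 0 and a warning.  Likewise a best correlation
    below ``min_score`` (uncorrelated content, e.g. pure noise) falls
    back to the nominal offset, reporting the low score, with a warning.
    """
    if strip_b.strip_index != strip_a.strip_index + 1:
        raise ValueError("strips must be adjacent (strip_b right of strip_a)")
    if strip_a.section_index != strip_b.section_index or strip_a.channel != strip_b.channel:
        raise ValueError("strips must come from the same section and channel")
    a = strip_a.pixels
    b = strip_b.pixels
    nominal = strip_a.width - strip_a.nominal_overlap_px
    h = min(strip_a.height, strip_b.height)

    band = a[:h, max(nominal - search_radius_px, 0) :]
    if np.ptp(band) == 0 or np.ptp(b[:h, : strip_a.width - nominal + search_radius_px]) == 0:
        warnings.warn(
            f"flat overlap band between strips {strip_a.strip_index} and "
            f"{strip_b.strip_index}; returning nominal offset"
        )
        return 0, nominal, 0.0

    best = (0, nominal, -np.inf)
    for d_col in range(nominal - search_radius_px, nominal + search_radius_px + 1):
        ov = strip_a.width - d_col  # implied overlap width
        if ov <= 0 or d_col < 0:
            continue
        ov = min(ov, strip_b.width)
        for d_row in range(-row_search_px, row_search_px + 1):
            a_r0 = max(d_row, 0)
            b_r0 = max(-d_row, 0)
            rows = min(strip_a.height - a_r0, strip_b.height - b_r0)
            if rows <= 0:
                continue
            band_a = a[a_r0 : a_r0 + rows, d_col : d_col + ov]
            band_b = b[b_r0 : b_r0 + rows, :ov]
            score = _ncc(band_a, band_b)
            if score > best[2]:
                best = (d_row, d_col, score)
    if not np.isfinite(best[2]):
        return 0, nominal, 0.0
    if best[2] < min_score:
        warnings.warn(
            f"overlap correlation {best[2]:.3f} below {min_score}; "
            f"falling back to the nominal offset for strips "
            f"{strip_a.strip_index}-{strip_b.strip_index}"
        )
        return 0, nominal, best[2]
    return best


def stitch_section(
    strips: list[StripImage],
    offsets: list[tuple[int, int]] | None = None,
    policy: str = "cut",
) -> SectionImage:
    """Assemble strips into one section image.

    ``offsets`` holds one (d_row, d_col) pair per adjacent strip pair
    (origin of the right strip relative to the left); ``None`` uses the
    nominal overlap.  Policy ``cut`` keeps the left strip up to the
    midpoint of each overlap zone and the right strip after it; ``feather``
    blends linearly across the zone.  The output height is the
    intersection of the vertically aligned rows.
    """
    if not strips:
        raise ValueError("no strips to stitch")
    if policy not in ("cut", "feather"):
        raise ValueError(f"unknown policy {policy!r}")
    if offsets is None:
        offsets = [(0, s.width - s.nominal_overlap_px) for s in strips[:-1]]
    if len(offsets) != len(strips) - 1:
        raise ValueError("need exactly one offset per adjacent strip pair")

    # cumulative placements
    cols = [0]
    rows = [0]
    for (d_row, d_col) in offsets:
        rows.append(rows[-1] + d_row)
        cols.append(cols[-1] + d_col)
    for i in range(len(strips) - 1):
        overlap = cols[i] + strips[i].width - cols[i + 1]
        if overlap < 0:
            raise StitchGapError(
                f"gap of {-overlap} px between strips "
                f"{strips[i].strip_index} and {strips[i + 1].strip_index}"
            )

    # common rows across all strips after vertical alignment
    row_lo = max(rows)
    row_hi = min(r + s.height for r, s in zip(rows, strips))
    if row_hi <= row_lo:
        raise ValueError("strips share no common rows after vertical alignment")
    height = row_hi - row_lo
    width = cols[-1] + strips[-1].width
    dtype = strips[0].pixels.dtype

    if policy == "cut":
        out = np.zeros((height, width), dtype=dtype)
        provenance = []
        # column where each strip starts contributing
        cut_starts = [0]
        for i in range(1, len(strips)):
            zone_lo = cols[i]
            zone_hi = cols[i - 1] + strips[i - 1].width
            cut_starts.append(zone_lo + (zone_hi - zone_lo) // 2)
        cut_ends = cut_starts[1:] + [width]
        for i, s in enumerate(strips):
            c0, c1 = cut_starts[i], cut_ends[i]
            r0 = row_lo - rows[i]
            out[:, c0:c1] = s.pixels[r0 : r0 + height, c0 - cols[i] : c1 - cols[i]]
            provenance.append((s.strip_index, (c0, c1)))
    else:  # feather
        acc = np.zeros((height, width), dtype=np.float64)
        wsum = np.zeros(width, dtype=np.float64)
        for i, s in enumerate(strips):
            r0 = row_lo - rows[i]
            w = np.ones(s.width, dtype=np.float64)
            if i > 0:
                ov = cols[i - 1] + strips[i - 1].width - cols[i]
                if ov > 0:
                    w[:ov] = np.linspace(0.0, 1.0, ov + 2)[1:-1]
            if i < len(strips) - 1:
                ov = cols[i] + s.width - cols[i + 1]
                if ov > 0:
                    w[s.width - ov :] = np.linspace(1.0, 0.0, ov + 2)[1:-1]
            acc[:, cols[i] : cols[i] + s.width] += s.pixels[r0 : r0 + height] * w
            wsum[cols[i] : cols[i] + s.width] += w
        out_f = acc / wsum[None, :]
        if np.issubdtype(dtype, np.integer):
            out = np.clip(np.rint(out_f), np.iinfo(dtype).min, np.iinfo(dtype).max).astype(dtype)
        else:
            out = out_f.astype(dtype)
        provenance = [
            (s.strip_index, (cols[i], cols[i] + s.width)) for i, s in enumerate(strips)
        ]

    return SectionImage(
        pixels=out,
        section_index=strips[0].section_index,
        channel=strips[0].channel,
        pixel_size_um=strips[0].pixel_size_um,
        provenance=provenance,
    )


def load_strips(strip_dir) -> dict[tuple[str, int], list[StripImage]]:
    """Read strip TIFFs with JSON sidecars (as written by the phantom
    module) into lists keyed by (channel, section), ordered by strip index."""
    strip_dir = Path(strip_dir)
    out: dict[tuple[str, int], list[StripImage]] = {}
    for sidecar in sorted(strip_dir.glob("*.json")):
        meta = json.loads(sidecar.read_text())
        pixels = tifffile.imread(sidecar.with_suffix(".tif"))
        strip = StripImage(
            pixels=pixels,
            channel=meta["channel"],
            section_index=int(meta["section_index"]),
            strip_index=int(meta["strip_index"]),
            nominal_overlap_px=int(meta["nominal_overlap_px"]),
            pixel_size_um=tuple(meta.get("pixel_size_um", (0.32, 0.32))),
            scan_reversed=bool(meta.get("scan_reversed", False)),
        )
        out.setdefault((strip.channel, strip.section_index), []).append(strip)
    for strips in out.values():
        strips.sort(key=lambda s: s.strip_index)
    return out


def stitch_directory(
    strip_dir,
    out_dir,
    policy: str = "cut",
    search_radius_px: int = 10,
    use_nominal: bool = False,
):
    """Stitch every (channel, section) found in ``strip_dir``; write section
    TIFFs and an offsets CSV.  Returns the offsets table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (channel, z), strips in sorted(load_strips(strip_dir).items()):
        offsets = []
        for a, b in zip(strips, strips[1:]):
            if use_nominal:
                d_row, d_col, score = 0, a.width - a.nominal_overlap_px, float("nan")
            else:
                d_row, d_col, score = estimate_offset(a, b, search_radius_px)
            offsets.append((d_row, d_col))
            rows.append(
                {
                    "channel": channel,
                    "section": z,
                    "pair": f"{a.strip_index}-{b.strip_index}",
                    "d_row": d_row,
                    "d_col": d_col,
                    "score": score,
                }
            )
        section = stitch_section(strips, offsets, policy=policy)
        tifffile.imwrite(out_dir / f"{channel}_{z:05d}.tif", section.pixels)
    table = pd.DataFrame(rows, columns=["channel", "section", "pair", "d_row", "d_col", "score"])
    table.to_csv(out_dir / "offsets.csv", index=False)
    return table
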