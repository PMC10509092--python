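"""AHA 16-segment mapping of short-axis scar masks.

The stack is split base -> apex into three contiguous level groups (basal,
mid, apical) as equal as possible, remainder assigned basally first.
Within a slice, the angle of each myocardial pixel is measured around the
centroid of the epicardial contour, zero at the anterior RV insertion
point, increasing through the anterior -> anteroseptal segment order.
Basal and mid levels use six 60-degree sectors (segments 1-6, 7-12),
the apical level four 90-degree sectors (segments 13-16); the apical cap
(segment 17) is not part of the 16-segment model.  Per-segment LGE extent
is area-weighted across the slices a segment spans, and allocated to five
ordinal categories: 0 (no LGE), 1 (0-25%], 2 (25-50%], 3 (50-75%],
4 (75-100%].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, InvalidParameterError
from .geometry import SliceGeometry
from .quantify import SliceQuant, SliceContours

__all__ = [
    "SegmentExtent",
    "split_levels",
    "assign_segments",
    "segment_extents",
    "segment_extent_category",
]

LEVEL_NAMES = ("basal", "mid", "apical")
# first segment id and sector width (degrees) per level
_LEVEL_LAYOUT = {"basal": (1, 60.0), "mid": (7, 60.0), "apical": (13, 90.0)}


@dataclass
class SegmentExtent:
    segment_id: int  # 1..16
    myo_area: float  # mm^2, summed over the segment's slices
    scar_area: float  # mm^2
    extent: float  # %, 0 when the segment has no myocardial area
    category: int  # ordinal 0..4


def split_levels(n_slices: int) -> list[str]:
    """Level name per slice, base -> apex; remainder goes basally first."""
    if n_slices < 3:
        raise InvalidParameterError(f"need >= 3 slices for level split, got {n_slices}")
    counts = [n_slices // 3] * 3
    for i in range(n_slices % 3):
        counts[i] += 1
    out: list[str] = []
    for name, cnt in zip(LEVEL_NAMES, counts):
        out.extend([name] * cnt)
    return out


def _insertion_angle(
    geometry: SliceGeometry, contours: SliceContours, insertion_world: np.ndarray
) -> tuple[float, float, float]:
    """Centroid (x, y) of the epicardial contour and the insertion azimuth."""
    cx, cy = contours.epi.centroid.x, contours.epi.centroid.y
    d = np.asarray(insertion_world, dtype=float) - geometry.origin
    ix = float(d @ geometry.row_dir)
    iy = float(d @ geometry.col_dir)
    theta0 = np.degrees(np.arctan2(iy - cy, ix - cx))
    return cx, cy, theta0


def assign_segments(
    geometries: Sequence[SliceGeometry],
    contours: Sequence[SliceContours],
    per_slice: Sequence[SliceQuant],
    rv_insertion: np.ndarray | Sequence[np.ndarray],
    clockwise: bool = False,
) -> list[np.ndarray]:
    """Per-pixel AHA segment labels for every slice (0 = not myocardium).

    ``rv_insertion`` is the world-coordinate anterior RV insertion point,
    one per slice or a single point propagated to all slices.  Angles
    advance counterclockwise in the slice frame by default
    (``clockwise=True`` flips the chirality for stacks viewed from the
    base).  Every myocardial pixel receives exactly one segment id.
    """
    n = len(per_slice)
    if not (len(geometries) == len(contours) == n):
        raise ConfigError("geometries, contours and per_slice must align")
    ins = np.asarray(rv_insertion, dtype=float)
    if ins.ndim == 1:
        ins_pts = [ins] * n
    else:
        if len(ins) != n:
            raise ConfigError(
                f"{len(ins)} insertion points for {n} slices (need one or one-per-slice)"
            )
        ins_pts = list(ins)
    levels = split_levels(n)
    chi = -1.0 if clockwise else 1.0

    labels: list[np.ndarray] = []
    for geom, ctr, quant, level, ip in zip(geometries, contours, per_slice, levels, ins_pts):
        first_id, width = _LEVEL_LAYOUT[level]
        n_sectors = int(round(360.0 / width))
        cx, cy, theta0 = _insertion_angle(geom, ctr, ip)
        xx, yy = geom.pixel_centers_plane()
        theta = np.degrees(np.arctan2(yy - cy, xx - cx))
        rel = np.mod(chi * (theta - theta0), 360.0)
        sector = np.minimum((rel // width).astype(int), n_sectors - 1)
        lab = np.where(quant.myo_mask, first_id + sector, 0)
        labels.append(lab)
    return labels


def segment_extents(
    per_slice: Sequence[SliceQuant],
    labels: Sequence[np.ndarray],
    pixel_areas: Sequence[float],
) -> list[SegmentExtent]:
    """Area-weighted per-segment LGE extent and ordinal category.

    Areas are pooled over all slices contributing to a segment before the
    ratio is taken, so thin apical slices do not dominate.
    """
    myo = np.zeros(17)
    scar = np.zeros(17)
    for quant, lab, area in zip(per_slice, labels, pixel_areas):
        counts_myo = np.bincount(lab[quant.myo_mask], minlength=17)
        counts_scar = np.bincount(lab[quant.scar_mask], minlength=17)
        myo += counts_myo * area
        scar += counts_scar * area
    out = []
    for seg in range(1, 17):
        extent = 100.0 * scar[seg] / myo[seg] if myo[seg] > 0 else 0.0
        out.append(
            SegmentExtent(
                segment_id=seg,
                myo_area=float(myo[seg]),
                scar_area=float(scar[seg]),
                extent=float(extent),
                category=segment_extent_category(extent),
            )
        )
    return out


def segment_extent_category(extent: float) -> int:
    """Ordinal LGE-extent category: 0 iff 0%, then (0,25] -> 1, (25,50] -> 2,
    (50,75] -> 3, (75,100] -> 4."""
    if not np.isfinite(extent) or extent < 0 or extent > 100:
        raise InvalidParameterError(f"extent must be in [0, 100], got {extent}")
    if extent == 0:
        return 0
    for cat, upper in enumerate((25.0, 50.0, 75.0, 100.0), start=1):
        if extent <= upper:
            return cat
    raise AssertionError("unreachable")
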