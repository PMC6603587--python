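"""Clinical outputs: per-slice lesion descriptors and a stacked 3D summary.

Lesions are 8-connected class-3 components in-plane; across the slice stack
they are merged 26-connected, so footprints overlapping in adjacent slices
become one 3D group.  The default inter-slice spacing of 4.4 mm is slice
thickness (3.4 mm) plus gap (1 mm); in-plane spacing must be supplied (the
acquisition does not state one — 0.5 mm/px is this tool's documented default
elsewhere, never assumed here).

The sub-1.5 cm small-vessel criterion is reported as a flag only; it never
suppresses a detection.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .errors import ShapeError
from .image_io import GrayscaleSlice, LabelMap, render_overlay
from PIL import Image

__all__ = [
    "SMALL_VESSEL_MAX_DIAMETER_MM",
    "DEFAULT_INTER_SLICE_SPACING_MM",
    "LesionRecord",
    "Lesion3D",
    "VolumeReport",
    "find_lesions",
    "stack_slices",
    "write_report",
    "read_report",
]

SMALL_VESSEL_MAX_DIAMETER_MM = 15.0
#: 3.4 mm slice thickness + 1.0 mm gap
DEFAULT_INTER_SLICE_SPACING_MM = 4.4

_EXACT_DIAMETER_MAX_PX = 10_000


@dataclass
class LesionRecord:
    """One in-plane lesion component.

    ``bbox`` is half-open ``(row_min, col_min, row_max, col_max)``;
    ``max_diameter_mm`` is the longest pairwise distance between member pixel
    centers times the pixel spacing.
    """

    slice_index: int
    component_id: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    area_px: int
    area_mm2: float
    max_diameter_mm: float
    small_vessel_flag: bool


@dataclass
class Lesion3D:
    group_id: int
    members: list[LesionRecord]
    volume_mm3: float
    centroid: tuple[float, float, float]  # (slice, row, col)


@dataclass
class VolumeReport:
    pixel_spacing_mm: float
    inter_slice_spacing_mm: float
    n_slices: int
    lesions_3d: list[Lesion3D] = field(default_factory=list)


def _max_diameter_px(rows: np.ndarray, cols: np.ndarray) -> float:
    """Longest pairwise distance between pixel centers."""
    points = np.column_stack([rows, cols]).astype(np.float64)
    if len(points) == 1:
        return 0.0
    if len(points) > _EXACT_DIAMETER_MAX_PX:
        # hull vertices suffice: the diameter is attained on the convex hull
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # collinear clouds make qhull unhappy
            pass
    return float(pdist(points).max())


def _find_lesions_with_pixels(
    labelmap: LabelMap, pixel_spacing_mm: float, slice_index: int
) -> list[tuple[LesionRecord, np.ndarray, np.ndarray]]:
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel_spacing_mm must be positive")
    lesion_mask = labelmap.classes == 3
    labels, count = ndimage.label(lesion_mask, structure=np.ones((3, 3), dtype=bool))
    found = []
    for comp in range(1, count + 1):
        rows, cols = np.nonzero(labels == comp)
        area_px = len(rows)
        diameter = _max_diameter_px(rows, cols) * pixel_spacing_mm
        record = LesionRecord(
            slice_index=slice_index,
            component_id=comp,
            centroid=(float(rows.mean()), float(cols.mean())),
            bbox=(int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1),
            area_px=area_px,
            area_mm2=area_px * pixel_spacing_mm**2,
            max_diameter_mm=diameter,
            small_vessel_flag=diameter < SMALL_VESSEL_MAX_DIAMETER_MM,
        )
        found.append((record, rows, cols))
    found.sort(key=lambda item: (-item[0].area_px, item[0].centroid[0], item[0].centroid[1]))
    for new_id, (record, _, _) in enumerate(found, start=1):
        record.component_id = new_id
    return found


def find_lesions(
    labelmap: LabelMap, pixel_spacing_mm: float, slice_index: int = 0
) -> list[LesionRecord]:
    """One record per 8-connected class-3 component, largest area first
    (ties: row-major centroid order)."""
    return [rec for rec, _, _ in _find_lesions_with_pixels(labelmap, pixel_spacing_mm, slice_index)]


def stack_slices(
    maps: list[LabelMap],
    pixel_spacing_mm: float,
    inter_slice_spacing_mm: float = DEFAULT_INTER_SLICE_SPACING_MM,
) -> VolumeReport:
    """Link in-plane lesions across adjacent slices into 3D groups.

    Grouping is 26-connected on the stacked voxel grid, so one pixel of
    footprint overlap (or diagonal touch) in an adjacent slice merges two
    records.  ``volume_mm3`` = sum of member areas x inter-slice spacing.
    """
    if not maps:
        raise ShapeError("need at least one label map")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ShapeError("all label maps must share the same dimensions")
    stack = np.stack([m.classes == 3 for m in maps])
    labels3d, count = ndimage.label(stack, structure=np.ones((3, 3, 3), dtype=bool))

    groups: dict[int, list[LesionRecord]] = {g: [] for g in range(1, count + 1)}
    for z, labelmap in enumerate(maps):
        for record, rows, cols in _find_lesions_with_pixels(labelmap, pixel_spacing_mm, z):
            # every pixel of a 2D component carries the same 3D group id
            gid = int(labels3d[z, rows[0], cols[0]])
            groups[gid].append(record)
    lesions_3d = []
    for gid in sorted(groups):
        members = groups[gid]
        if not members:
            continue
        total_area = sum(m.area_mm2 for m in members)
        weights = np.array([m.area_px for m in members], dtype=np.float64)
        zs = np.array([m.slice_index for m in members], dtype=np.float64)
        rs = np.array([m.centroid[0] for m in members])
        cs = np.array([m.centroid[1] for m in members])
        centroid = (
            float(np.average(zs, weights=weights)),
            float(np.average(rs, weights=weights)),
            float(np.average(cs, weights=weights)),
        )
        lesions_3d.append(
            Lesion3D(
                group_id=len(lesions_3d) + 1,
                members=members,
                volume_mm3=total_area * inter_slice_spacing_mm,
                centroid=centroid,
            )
        )
    return VolumeReport(
        pixel_spacing_mm=pixel_spacing_mm,
        inter_slice_spacing_mm=inter_slice_spacing_mm,
        n_slices=len(maps),
        lesions_3d=lesions_3d,
    )


def write_report(
    report: VolumeReport | list[LesionRecord],
    path: str,
    slices: list[GrayscaleSlice] | None = None,
    maps: list[LabelMap] | None = None,
    overlay_dir: str | None = None,
) -> None:
    """Serialize to JSON (schema version 1); optionally emit overlay PNGs."""
    if isinstance(report, VolumeReport):
        payload = {"schema_version": 1, "kind": "volume", **asdict(report)}
    else:
        payload = {"schema_version": 1, "kind": "slices", "lesions": [asdict(r) for r in report]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    if overlay_dir is not None and slices is not None and maps is not None:
        os.makedirs(overlay_dir, exist_ok=True)
        for i, (slc, lm) in enumerate(zip(slices, maps)):
            rgb = render_overlay(slc, lm, style="fill")
            Image.fromarray(rgb, mode="RGB").save(os.path.join(overlay_dir, f"overlay_{i:04d}.png"))


def read_report(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
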