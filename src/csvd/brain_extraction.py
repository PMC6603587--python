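"""Rule-based brain extraction for 2D head slices.

The pipeline removes the bright cranium ring and the exterior background,
keeping only intracranial content:

1. binarize (cranium must be the largest foreground component)
2. label connected components, delete the largest (the cranium)
3. inverse-binarize at the same threshold
4. union of steps 2 and 3, restricted to components contained in the
   removed cranium's bounding box
5. binary median filtering
6. geometry (bounding box, centroid, areas) of the final mask

Masks are plain boolean arrays; every intermediate is retained on the
result object for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import (
    ConfigError,
    DegenerateImageError,
    EmptyMaskError,
    NoBrainFoundError,
    ShapeError,
)
from .image_io import GrayscaleSlice

__all__ = [
    "BinaryMask",
    "ComponentSet",
    "BrainRegion",
    "ExtractionConfig",
    "BrainExtractionResult",
    "resolve_threshold",
    "binarize",
    "inverse_binarize",
    "label_components",
    "remove_largest",
    "combine_regions",
    "median_filter_mask",
    "brain_geometry",
    "extract_brain",
]

BinaryMask = np.ndarray  # 2D bool
ThresholdPolicy = Union[str, float, int]  # "otsu" | numeric fixed threshold

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity not in _STRUCTURES:
        raise ConfigError(f"connectivity must be 4 or 8, got {connectivity}")
    return _STRUCTURES[connectivity]


def _as_pixels(slc: GrayscaleSlice | np.ndarray) -> np.ndarray:
    return slc.pixels if isinstance(slc, GrayscaleSlice) else np.asarray(slc)


@dataclass
class ComponentSet:
    """Connected-component labeling of a binary mask.

    ``labels`` holds ids 1..count with 0 for background; ``areas[i]`` is the
    pixel count of component ``i + 1``.
    """

    labels: np.ndarray
    areas: np.ndarray
    count: int


@dataclass
class BrainRegion:
    """Geometry summary of a brain mask.

    ``bbox`` is half-open ``(row_min, col_min, row_max, col_max)``; the
    centroid is the mean of foreground coordinates in fractional pixels.
    ``area_mm2`` is present only when pixel spacing is known.
    """

    mask: BinaryMask
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    area_px: int
    area_mm2: float | None = None


@dataclass
class ExtractionConfig:
    threshold_policy: ThresholdPolicy = "otsu"
    connectivity: int = 8
    median_kernel: int = 3


@dataclass
class BrainExtractionResult:
    region: BrainRegion
    masked: GrayscaleSlice
    threshold: float
    cranium_bbox: tuple[int, int, int, int]
    intermediates: dict[str, BinaryMask] = field(default_factory=dict)


def resolve_threshold(slc: GrayscaleSlice | np.ndarray, policy: ThresholdPolicy) -> float:
    """Turn a threshold policy into a concrete intensity value.

    Otsu requires at least two distinct intensities; constant images raise
    :class:`DegenerateImageError`.
    """
    pixels = _as_pixels(slc)
    if isinstance(policy, str):
        if policy != "otsu":
            raise ConfigError(f"unknown threshold policy {policy!r}")
        if np.ptp(pixels) == 0:
            raise DegenerateImageError("constant image: Otsu threshold is undefined")
        # skimage's convention is foreground = pixels > t; ours is >= t, so
        # shift to the smallest observed intensity strictly above t
        t = threshold_otsu(pixels)
        values = np.unique(pixels)
        return float(values[values > t].min())
    return float(policy)


def binarize(slc: GrayscaleSlice | np.ndarray, threshold_policy: ThresholdPolicy = "otsu") -> BinaryMask:
    """Foreground mask: cell is 1 iff intensity >= threshold."""
    pixels = _as_pixels(slc)
    return pixels >= resolve_threshold(pixels, threshold_policy)


def inverse_binarize(
    slc: GrayscaleSlice | np.ndarray, threshold_policy: ThresholdPolicy = "otsu"
) -> BinaryMask:
    """Complement of :func:`binarize` at the same threshold."""
    return ~binarize(slc, threshold_policy)


def label_components(mask: BinaryMask, connectivity: int = 8) -> ComponentSet:
    """Label connected foreground components; areas are exact pixel counts."""
    structure = _connectivity_structure(connectivity)
    labels, count = ndimage.label(np.asarray(mask, dtype=bool), structure=structure)
    areas = np.bincount(labels.ravel(), minlength=count + 1)[1:]
    return ComponentSet(labels=labels, areas=areas, count=int(count))


def remove_largest(mask: BinaryMask, connectivity: int = 8) -> BinaryMask:
    """Delete the single maximum-area component (ties: lowest id, i.e. first
    encountered in row-major scan order)."""
    comps = label_components(mask, connectivity)
    if comps.count == 0:
        raise EmptyMaskError("mask has no foreground component")
    largest = int(np.argmax(comps.areas)) + 1
    return np.asarray(mask, dtype=bool) & (comps.labels != largest)


def _component_bbox(sel: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.any(sel, axis=1)
    cols = np.any(sel, axis=0)
    r = np.where(rows)[0]
    c = np.where(cols)[0]
    return int(r[0]), int(c[0]), int(r[-1]) + 1, int(c[-1]) + 1


def combine_regions(
    a: BinaryMask,
    b: BinaryMask,
    cranium_bbox: tuple[int, int, int, int] | None = None,
    connectivity: int = 8,
) -> BinaryMask:
    """Elementwise OR, optionally restricted to intracranial components.

    With ``cranium_bbox`` given, only components of the union that lie
    entirely inside the (half-open) box are kept.  The raw OR also contains
    the exterior background — below threshold just like brain tissue — and
    that component always spills past the cranium's box, so containment is
    what separates intracranial from exterior content.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = a | b
    if cranium_bbox is None:
        return union
    r0, c0, r1, c1 = cranium_bbox
    comps = label_components(union, connectivity)
    keep = np.zeros(comps.count + 1, dtype=bool)
    slices = ndimage.find_objects(comps.labels)
    for idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        rs, cs = sl
        keep[idx] = rs.start >= r0 and cs.start >= c0 and rs.stop <= r1 and cs.stop <= c1
    return keep[comps.labels]


def median_filter_mask(mask: BinaryMask, kernel: int = 3) -> BinaryMask:
    """Per-cell median over a kernel x kernel neighborhood (edge-replicated)."""
    if kernel % 2 == 0 or kernel < 3:
        raise ConfigError(f"median kernel must be odd and >= 3, got {kernel}")
    filtered = ndimage.median_filter(
        np.asarray(mask, dtype=np.uint8), size=kernel, mode="nearest"
    )
    return filtered.astype(bool)


def brain_geometry(mask: BinaryMask, pixel_spacing_mm: float | None = None) -> BrainRegion:
    """Tight bounding box, centroid and area of a non-empty mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot compute geometry of an empty mask")
    rows, cols = np.nonzero(mask)
    bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
    centroid = (float(rows.mean()), float(cols.mean()))
    area_px = int(mask.sum())
    area_mm2 = area_px * pixel_spacing_mm**2 if pixel_spacing_mm is not None else None
    return BrainRegion(mask=mask, bbox=bbox, centroid=centroid, area_px=area_px, area_mm2=area_mm2)


def extract_brain(
    slc: GrayscaleSlice, config: ExtractionConfig | None = None
) -> BrainExtractionResult:
    """Run the full six-step extraction; intermediates mirror each step.

    Returns the final :class:`BrainRegion` plus the slice with everything
    outside the brain mask zeroed.  Raises :class:`NoBrainFoundError` when
    the final mask is empty.
    """
    cfg = config or ExtractionConfig()
    threshold = resolve_threshold(slc, cfg.threshold_policy)
    step1 = binarize(slc, threshold)
    comps = label_components(step1, cfg.connectivity)
    if comps.count == 0:
        raise NoBrainFoundError("binarization produced no foreground at all")
    largest = int(np.argmax(comps.areas)) + 1
    cranium = comps.labels == largest
    cranium_bbox = _component_bbox(cranium)
    step2 = step1 & ~cranium
    step3 = ~step1
    step4 = combine_regions(step2, step3, cranium_bbox=cranium_bbox, connectivity=cfg.connectivity)
    step5 = median_filter_mask(step4, cfg.median_kernel)
    # the cranium itself must never survive, whatever the filter does at edges
    step5 = step5 & ~cranium
    if not step5.any():
        raise NoBrainFoundError("extraction produced an empty brain mask")
    region = brain_geometry(step5, slc.pixel_spacing_mm)
    masked = GrayscaleSlice(
        np.where(step5, slc.pixels, 0),
        pixel_spacing_mm=slc.pixel_spacing_mm,
        slice_index=slc.slice_index,
    )
    return BrainExtractionResult(
        region=region,
        masked=masked,
        threshold=threshold,
        cranium_bbox=cranium_bbox,
        intermediates={
            "binarized": step1,
            "cranium": cranium,
            "shell_removed": step2,
            "inverse": step3,
            "union": step4,
            "median": step5,
        },
    )
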