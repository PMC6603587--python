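"""Slice and label-map I/O plus the 4-color ground-truth convention.

Coordinates are 0-based ``(row, col)``, row-major, row 0 at the image top.
Intensities are kept in their native integer range; nothing here rescales
silently (the classifier applies an explicit rescale of its own).

Label classes::

    0  non-brain   black (0, 0, 0)
    1  normal brain  green (0, 255, 0)
    2  central brain  blue  (0, 0, 255)
    3  lesion       red   (255, 0, 0)
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, UnidentifiedImageError

from . import _dicom
from .errors import FormatError, LabelDecodeError, ShapeError, UnsupportedInputError

__all__ = [
    "GrayscaleSlice",
    "LabelMap",
    "CLASS_COLORS",
    "N_CLASSES",
    "read_slice",
    "write_slice",
    "decode_labelmap",
    "encode_labelmap",
    "read_labelmap",
    "write_labelmap",
    "render_overlay",
]

N_CLASSES = 4

#: class id -> RGB triple; bijective over the 4 classes.
CLASS_COLORS: dict[int, tuple[int, int, int]] = {
    0: (0, 0, 0),
    1: (0, 255, 0),
    2: (0, 0, 255),
    3: (255, 0, 0),
}

_PALETTE = np.array([CLASS_COLORS[c] for c in range(N_CLASSES)], dtype=np.int64)


@dataclass
class GrayscaleSlice:
    """A single 2D intensity grid, optionally carrying acquisition metadata.

    Parameters
    ----------
    pixels
        2D array of finite, non-negative intensities (native integer range).
    pixel_spacing_mm
        In-plane edge length of one pixel, if known.
    slice_index
        Ordinal position in the acquisition stack, if known.
    """

    pixels: np.ndarray
    pixel_spacing_mm: float | None = None
    slice_index: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ShapeError(f"slice must be a non-empty 2D grid, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("slice intensities must be finite and non-negative")
        if self.pixel_spacing_mm is not None and self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMap:
    """Per-pixel class assignment over the 4-class scheme."""

    classes: np.ndarray

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2 or self.classes.size == 0:
            raise ShapeError(f"label map must be a non-empty 2D grid, got shape {self.classes.shape}")
        if self.classes.dtype.kind not in "iu":
            if not np.all(self.classes == np.round(self.classes)):
                raise ValueError("label map entries must be integers")
            self.classes = self.classes.astype(np.int64)
        if self.classes.min() < 0 or self.classes.max() >= N_CLASSES:
            raise ValueError("label map entries must lie in {0, 1, 2, 3}")

    @property
    def height(self) -> int:
        return self.classes.shape[0]

    @property
    def width(self) -> int:
        return self.classes.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    def __eq__(self, other: object) -> bool:  # value semantics for tests
        if not isinstance(other, LabelMap):
            return NotImplemented
        return self.classes.shape == other.classes.shape and bool(
            np.all(self.classes == other.classes)
        )


def _infer_format(path: str, format: str | None) -> str:
    if format is not None:
        return format.lower()
    ext = os.path.splitext(path)[1].lower()
    return {
        ".dcm": "dicom",
        ".dicom": "dicom",
        ".png": "png",
        ".tif": "tiff",
        ".tiff": "tiff",
    }.get(ext, "png")


def read_slice(path: str, format: str | None = None) -> GrayscaleSlice:
    """Read a single-frame grayscale image or DICOM file.

    Integer intensities are preserved losslessly.  DICOM pixel spacing is
    propagated when present; PNG/TIFF slices carry no spacing.

    Raises
    ------
    FormatError
        Unreadable or unparsable file.
    UnsupportedInputError
        RGB/palette image or multi-frame DICOM.
    """
    fmt = _infer_format(path, format)
    if fmt == "dicom":
        pixels, spacing, index = _dicom.read(path)
        return GrayscaleSlice(pixels, pixel_spacing_mm=spacing, slice_index=index)
    if fmt not in ("png", "tiff"):
        raise FormatError(f"unknown format {fmt!r}")
    try:
        with Image.open(path) as im:
            n_frames = getattr(im, "n_frames", 1)
            if n_frames > 1:
                raise UnsupportedInputError(f"{path}: multi-frame image ({n_frames} frames)")
            if im.mode not in ("L", "I", "I;16", "I;16B", "F", "1"):
                raise UnsupportedInputError(f"{path}: mode {im.mode!r} is not grayscale")
            arr = np.asarray(im)
    except UnidentifiedImageError as exc:
        raise FormatError(f"{path}: not a readable {fmt} image") from exc
    except OSError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return GrayscaleSlice(arr)


def write_slice(slc: GrayscaleSlice, path: str, format: str | None = None) -> None:
    """Write a slice; integer grids round-trip bit-identically.

    8-bit data goes out as mode ``L``, wider integer data as 32-bit ``I``
    (PNG stores it as 16-bit, which is lossless up to 65535).
    """
    fmt = _infer_format(path, format)
    if fmt == "dicom":
        _dicom.write(path, slc.pixels, slc.pixel_spacing_mm, slc.slice_index)
        return
    arr = slc.pixels
    if arr.dtype.kind in "iu" and arr.max(initial=0) <= 255:
        im = Image.fromarray(arr.astype(np.uint8), mode="L")
    elif arr.dtype.kind in "iu" and arr.max(initial=0) <= 0xFFFF:
        im = Image.fromarray(arr.astype("<u2"))  # PIL infers I;16
    elif arr.dtype.kind in "iu":
        raise UnsupportedInputError("integer slices wider than 16 bit are not supported")
    else:
        im = Image.fromarray(arr.astype(np.float32), mode="F")
        if fmt == "png":
            raise UnsupportedInputError("float slices can only be written as TIFF")
    im.save(path, format="PNG" if fmt == "png" else "TIFF")


def decode_labelmap(rgb_image: np.ndarray, tolerance: float = 16.0) -> LabelMap:
    """Map an RGB annotation to class ids by nearest palette color.

    Each pixel is assigned the class of the nearest ``CLASS_COLORS`` entry
    (Euclidean distance in RGB space).  A default tolerance of 16/255 absorbs
    lossy edges of hand-drawn annotations; pass ``tolerance=0`` for exact mode.

    Raises
    ------
    LabelDecodeError
        Some pixel is farther than ``tolerance`` from all four palette
        colors; the error message reports the first offending coordinate.
    """
    rgb = np.asarray(rgb_image)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ShapeError(f"expected H x W x 3 RGB grid, got shape {rgb.shape}")
    rgb = rgb[:, :, :3].astype(np.int64)
    # (H, W, 4) distances to the palette
    diff = rgb[:, :, None, :] - _PALETTE[None, None, :, :]
    dist2 = np.sum(diff * diff, axis=-1)
    nearest = np.argmin(dist2, axis=-1)
    mindist = np.sqrt(np.min(dist2, axis=-1))
    bad = mindist > tolerance
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise LabelDecodeError(
            f"pixel at (row={r}, col={c}) with RGB {tuple(rgb[r, c])} is "
            f"{mindist[r, c]:.1f} > tolerance {tolerance} from every palette color"
        )
    return LabelMap(nearest.astype(np.int64))


def encode_labelmap(labelmap: LabelMap) -> np.ndarray:
    """Render a label map as an RGB grid; exact inverse of :func:`decode_labelmap`."""
    return _PALETTE[labelmap.classes].astype(np.uint8)


def read_labelmap(path: str, tolerance: float = 16.0) -> LabelMap:
    try:
        with Image.open(path) as im:
            rgb = np.asarray(im.convert("RGB"))
    except UnidentifiedImageError as exc:
        raise FormatError(f"{path}: not a readable image") from exc
    return decode_labelmap(rgb, tolerance=tolerance)


def write_labelmap(labelmap: LabelMap, path: str) -> None:
    Image.fromarray(encode_labelmap(labelmap), mode="RGB").save(path)


def _to_display_gray(pixels: np.ndarray) -> np.ndarray:
    """Clip/scale intensities into uint8 for display only (I/O stays lossless)."""
    arr = np.asarray(pixels, dtype=np.float64)
    top = arr.max(initial=0.0)
    if top > 255.0:
        arr = arr * (255.0 / top)
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def render_overlay(
    slc: GrayscaleSlice,
    labelmap: LabelMap,
    style: str = "fill",
    tint_classes: bool = False,
    tint_alpha: float = 0.25,
) -> np.ndarray:
    """Draw lesion pixels (class 3) in red over the grayscale slice.

    ``style="fill"`` paints every lesion pixel; ``style="outline"`` paints only
    lesion pixels with a non-lesion 4-neighbor (or on the image border).  With
    ``tint_classes``, classes 1 and 2 are alpha-blended with their palette
    colors as orientation aid.
    """
    if style not in ("fill", "outline"):
        raise ValueError(f"style must be 'fill' or 'outline', got {style!r}")
    if slc.shape != labelmap.shape:
        raise ShapeError(f"slice {slc.shape} and label map {labelmap.shape} differ")
    gray = _to_display_gray(slc.pixels)
    out = np.stack([gray, gray, gray], axis=-1).astype(np.float64)
    cls = labelmap.classes
    if tint_classes:
        for c in (1, 2):
            sel = cls == c
            color = np.array(CLASS_COLORS[c], dtype=np.float64)
            out[sel] = (1 - tint_alpha) * out[sel] + tint_alpha * color
    lesion = cls == 3
    if style == "outline" and lesion.any():
        interior = np.zeros_like(lesion)
        interior[1:-1, 1:-1] = (
            lesion[1:-1, 1:-1]
            & lesion[:-2, 1:-1]
            & lesion[2:, 1:-1]
            & lesion[1:-1, :-2]
            & lesion[1:-1, 2:]
        )
        lesion = lesion & ~interior
    out[lesion] = np.array(CLASS_COLORS[3], dtype=np.float64)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
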