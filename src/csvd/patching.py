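"""Tiling slices into small square patches and reassembling patch decisions.

Default geometry is a non-overlapping 7x7 tiling: the image is padded with
zeros on the bottom/right edges only (keeping the (0, 0) origin stable for
coordinate reporting) so that patches partition the padded grid exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ShapeError
from .image_io import GrayscaleSlice, LabelMap, N_CLASSES

__all__ = ["PatchGrid", "PatchSet", "make_grid", "extract_patches", "assign_patch_labels", "reassemble"]

LABEL_RULES = ("majority_priority", "any_lesion")


@dataclass(frozen=True)
class PatchGrid:
    """Tiling geometry: patch size, stride and the padded canvas.

    ``padded_height``/``padded_width`` are the smallest multiples of the
    stride covering the original dims; ``rows``/``cols`` count grid cells.
    """

    original_height: int
    original_width: int
    patch_size: int = 7
    stride: int = 7
    pad_value: int = 0

    @property
    def rows(self) -> int:
        return -(-self.original_height // self.stride)

    @property
    def cols(self) -> int:
        return -(-self.original_width // self.stride)

    @property
    def padded_height(self) -> int:
        return self.rows * self.stride

    @property
    def padded_width(self) -> int:
        return self.cols * self.stride

    @property
    def n_patches(self) -> int:
        return self.rows * self.cols

    def footprint(self, grid_row: int, grid_col: int) -> tuple[slice, slice]:
        """Padded-canvas slice covered by patch (grid_row, grid_col)."""
        r0 = grid_row * self.stride
        c0 = grid_col * self.stride
        return slice(r0, r0 + self.patch_size), slice(c0, c0 + self.patch_size)


@dataclass
class PatchSet:
    """Row-major enumeration of patches with their grid positions.

    ``patches`` has shape (n, patch_size, patch_size); ``labels`` aligns 1:1
    with patches when present.
    """

    patches: np.ndarray
    positions: list[tuple[int, int]]
    grid: PatchGrid
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.patches) != len(self.positions):
            raise ShapeError("patches and positions must align 1:1")
        if self.labels is not None and len(self.labels) != len(self.patches):
            raise ShapeError("labels must align 1:1 with patches")

    def __len__(self) -> int:
        return len(self.patches)


def make_grid(height: int, width: int, patch_size: int = 7, stride: int | None = None, pad_value: int = 0) -> PatchGrid:
    if patch_size < 1:
        raise ConfigError(f"patch_size must be >= 1, got {patch_size}")
    if stride is None:
        stride = patch_size
    if stride < 1:
        raise ConfigError(f"stride must be >= 1, got {stride}")
    if height < 1 or width < 1:
        raise ConfigError(f"image dims must be positive, got {height}x{width}")
    return PatchGrid(height, width, patch_size=patch_size, stride=stride, pad_value=pad_value)


def _pad_to_grid(values: np.ndarray, grid: PatchGrid, pad_value) -> np.ndarray:
    """Pad bottom/right so every patch footprint is fully inside the canvas."""
    need_h = max(grid.padded_height, (grid.rows - 1) * grid.stride + grid.patch_size)
    need_w = max(grid.padded_width, (grid.cols - 1) * grid.stride + grid.patch_size)
    return np.pad(
        values,
        ((0, need_h - values.shape[0]), (0, need_w - values.shape[1])),
        mode="constant",
        constant_values=pad_value,
    )


def _values_of(image) -> np.ndarray:
    if isinstance(image, GrayscaleSlice):
        return image.pixels
    if isinstance(image, LabelMap):
        return image.classes
    return np.asarray(image)


def extract_patches(image, grid: PatchGrid) -> PatchSet:
    """Cut the image into row-major patches; padded cells hold ``pad_value``
    (class 0 for label maps)."""
    values = _values_of(image)
    if values.shape != (grid.original_height, grid.original_width):
        raise ShapeError(
            f"image shape {values.shape} does not match grid "
            f"{(grid.original_height, grid.original_width)}"
        )
    pad_value = 0 if isinstance(image, LabelMap) else grid.pad_value
    padded = _pad_to_grid(values, grid, pad_value)
    ps, st = grid.patch_size, grid.stride
    windows = np.lib.stride_tricks.sliding_window_view(padded, (ps, ps))[::st, ::st]
    patches = windows.reshape(-1, ps, ps).copy()
    positions = [(r, c) for r in range(grid.rows) for c in range(grid.cols)]
    return PatchSet(patches=patches, positions=positions, grid=grid)


def assign_patch_labels(truth: LabelMap, grid: PatchGrid, rule: str = "any_lesion") -> np.ndarray:
    """Per-patch ground-truth class.

    ``majority_priority``: most frequent class in the footprint, ties broken
    toward the higher class id (3 > 2 > 1 > 0).  ``any_lesion``: class 3 as
    soon as one lesion pixel is present, else majority_priority — the default,
    since lesions are rare and sub-patch sized and a plain majority vote would
    erase them.
    """
    if rule not in LABEL_RULES:
        raise ConfigError(f"unknown labeling rule {rule!r}; expected one of {LABEL_RULES}")
    patch_classes = extract_patches(truth, grid).patches
    n = len(patch_classes)
    flat = patch_classes.reshape(n, -1)
    counts = np.stack([(flat == c).sum(axis=1) for c in range(N_CLASSES)], axis=1)
    # ties toward higher id: reversed argmax picks the last maximal class
    labels = (N_CLASSES - 1) - np.argmax(counts[:, ::-1], axis=1)
    if rule == "any_lesion":
        labels = np.where(counts[:, 3] > 0, 3, labels)
    return labels.astype(np.int64)


def reassemble(labels: np.ndarray, grid: PatchGrid) -> LabelMap:
    """Paint each patch footprint with its class and crop padding.

    With overlapping strides later patches overwrite earlier ones (row-major
    order); with the default stride = patch_size the footprints partition the
    canvas and order is irrelevant.
    """
    labels = np.asarray(labels)
    if labels.shape != (grid.n_patches,):
        raise ShapeError(f"expected {grid.n_patches} labels, got shape {labels.shape}")
    if grid.stride == grid.patch_size:
        canvas = np.repeat(
            np.repeat(labels.reshape(grid.rows, grid.cols), grid.patch_size, axis=0),
            grid.patch_size,
            axis=1,
        )
    else:
        canvas = np.zeros(
            (
                max(grid.padded_height, (grid.rows - 1) * grid.stride + grid.patch_size),
                max(grid.padded_width, (grid.cols - 1) * grid.stride + grid.patch_size),
            ),
            dtype=np.int64,
        )
        for idx, (r, c) in enumerate((r, c) for r in range(grid.rows) for c in range(grid.cols)):
            canvas[grid.footprint(r, c)] = labels[idx]
    return LabelMap(canvas[: grid.original_height, : grid.original_width].astype(np.int64))
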