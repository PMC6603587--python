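"""Synthetic head-slice generator with exact ground truth.

Each phantom slice contains, from outside in: dark background, a bright
cranium ring, a dark gap, a textured brain disk, a darker central
(ventricle-like) ellipse, and 0-4 hyperintense lesion disks with smooth
edges, plus additive Gaussian noise clipped to [0, 255].  The paired label
map assigns class 0 to background *and* cranium (the labeling scheme has no
separate skull class), 1 to brain tissue, 2 to the central structure and 3
to lesions.

Geometry guarantees the extraction pipeline's assumptions: the ring is the
largest bright connected component and never touches the brain disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, PlacementError
from .image_io import GrayscaleSlice, LabelMap

__all__ = ["PhantomSpec", "PhantomDataset", "generate_slice", "generate_dataset", "scaled_spec"]

#: train/val/test proportions mirroring a 205/205/206 split of 616 images.
SPLIT_WEIGHTS = (205, 205, 206)
SPLIT_NAMES = ("train", "val", "test")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of the synthetic slices.

    Default intensity ordering is skull > lesion > brain > central >
    background; radii are fractions of the image size so a spec scales down
    for fast tests (pixel-valued knobs like ``skull_thickness_px`` must be
    adjusted alongside).
    """

    image_size: int = 512
    pixel_spacing_mm: float = 0.5
    skull_outer_radius_frac: float = 0.46
    skull_thickness_px: int = 60
    brain_radius_frac: float = 0.30
    central_axes_frac: tuple[float, float] = (0.10, 0.06)
    background_intensity: float = 20.0
    skull_intensity: float = 240.0
    brain_intensity: float = 110.0
    central_intensity: float = 45.0
    lesion_intensity: float = 200.0
    noise_sigma: float = 6.0
    lesion_count_range: tuple[int, int] = (0, 4)
    lesion_diameter_mm_range: tuple[float, float] = (2.0, 14.0)
    lesion_edge_px: float = 1.0
    center_jitter_frac: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ConfigError("image_size must be >= 32")
        for name in (
            "background_intensity",
            "skull_intensity",
            "brain_intensity",
            "central_intensity",
            "lesion_intensity",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 255:
                raise ConfigError(f"{name}={value} outside [0, 255]")
        lo, hi = self.lesion_diameter_mm_range
        if lo <= 0 or hi < lo:
            raise ConfigError("lesion_diameter_mm_range must satisfy 0 < lo <= hi")
        if hi >= 15.0:
            raise ConfigError("lesion diameters must stay strictly below 15 mm")
        lo_n, hi_n = self.lesion_count_range
        if lo_n < 0 or hi_n < lo_n:
            raise ConfigError("lesion_count_range must satisfy 0 <= lo <= hi")
        outer = self.skull_outer_radius_frac * self.image_size
        inner = outer - self.skull_thickness_px
        brain = self.brain_radius_frac * self.image_size
        if inner <= brain + 1:
            raise ConfigError("cranium ring would intersect the brain disk")
        if outer >= self.image_size / 2:
            raise ConfigError("cranium ring must fit inside the image")


@dataclass
class PhantomDataset:
    slices: list[GrayscaleSlice]
    truths: list[LabelMap]
    split: dict[str, list[int]]
    spec: PhantomSpec
    seed: int
    slice_seeds: list[int] = field(default_factory=list)


def scaled_spec(image_size: int = 512, **overrides) -> PhantomSpec:
    """A feasible spec at any image size.

    The stock defaults are tuned for 512x512; pixel-valued knobs (ring
    thickness) and, below 192 px, the spacing/lesion-size regime are rescaled
    so the geometry invariants keep holding.  Explicit ``overrides`` win.
    """
    if image_size >= 192:
        base: dict = {
            "image_size": image_size,
            "skull_thickness_px": max(8, round(60 * image_size / 512)),
        }
    else:
        base = {
            "image_size": image_size,
            "pixel_spacing_mm": 1.0,
            "skull_thickness_px": max(4, image_size // 8),
            "brain_radius_frac": 0.28,
            "lesion_count_range": (0, 3),
            "lesion_diameter_mm_range": (4.0, max(4.0, min(10.0, 0.45 * 0.28 * image_size))),
        }
    base.update(overrides)
    return PhantomSpec(**base)


def _place_lesions(
    rng: np.random.Generator,
    spec: PhantomSpec,
    center: tuple[float, float],
    max_retries: int = 200,
) -> list[tuple[float, float, float]]:
    """Uniform non-overlapping lesion centers inside the brain, clear of the
    central structure; returns (row, col, radius_px) triples."""
    count = int(rng.integers(spec.lesion_count_range[0], spec.lesion_count_range[1] + 1))
    if count == 0:
        return []
    brain_r = spec.brain_radius_frac * spec.image_size
    lo_px = spec.lesion_diameter_mm_range[0] / spec.pixel_spacing_mm / 2.0
    hi_px = spec.lesion_diameter_mm_range[1] / spec.pixel_spacing_mm / 2.0
    if hi_px >= brain_r - 2:
        raise PlacementError("lesion radius range does not fit inside the brain disk")
    placed: list[tuple[float, float, float]] = []
    ay, ax = (f * spec.image_size for f in spec.central_axes_frac)
    for _ in range(count):
        radius = float(rng.uniform(lo_px, hi_px))
        for _attempt in range(max_retries):
            # uniform in the disk of feasible centers
            theta = rng.uniform(0, 2 * np.pi)
            rho = (brain_r - radius - 2) * np.sqrt(rng.uniform())
            r = center[0] + rho * np.sin(theta)
            c = center[1] + rho * np.cos(theta)
            # clear of the central ellipse (with the lesion radius as margin)
            if ((r - center[0]) / (ay + radius)) ** 2 + ((c - center[1]) / (ax + radius)) ** 2 <= 1:
                continue
            if all(
                np.hypot(r - pr, c - pc) > radius + prad + 2 for pr, pc, prad in placed
            ):
                placed.append((r, c, radius))
                break
        else:
            raise PlacementError(
                f"could not place lesion {len(placed) + 1}/{count} after {max_retries} tries"
            )
    return placed


def generate_slice(
    spec: PhantomSpec, seed: int, slice_index: int | None = None
) -> tuple[GrayscaleSlice, LabelMap]:
    """Deterministic (slice, truth) pair for the given (spec, seed)."""
    rng = np.random.default_rng(seed)
    n = spec.image_size
    jitter = spec.center_jitter_frac * n
    center = (n / 2 + rng.uniform(-jitter, jitter), n / 2 + rng.uniform(-jitter, jitter))
    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64)
    dist = np.hypot(rr - center[0], cc - center[1])

    outer = spec.skull_outer_radius_frac * n
    inner = outer - spec.skull_thickness_px
    brain_r = spec.brain_radius_frac * n
    ring = (dist <= outer) & (dist >= inner)
    brain = dist <= brain_r
    ay, ax = (f * n for f in spec.central_axes_frac)
    central = (((rr - center[0]) / ay) ** 2 + ((cc - center[1]) / ax) ** 2) <= 1.0
    central &= brain

    classes = np.zeros((n, n), dtype=np.int64)
    classes[brain] = 1
    classes[central] = 2

    intensity = np.full((n, n), spec.background_intensity)
    intensity[brain] = spec.brain_intensity
    intensity[central] = spec.central_intensity
    intensity[ring] = spec.skull_intensity

    lesions = _place_lesions(rng, spec, center)
    for lr, lc, lrad in lesions:
        d = np.hypot(rr - lr, cc - lc)
        # smooth-edged disk: full contrast in the core, linear falloff over
        # lesion_edge_px; the label boundary sits at the half-contrast radius
        w = np.clip((lrad - d) / max(spec.lesion_edge_px, 1e-6) + 0.5, 0.0, 1.0)
        sel = w > 0
        intensity[sel] = intensity[sel] + w[sel] * (spec.lesion_intensity - intensity[sel])
        classes[(d <= lrad) & brain & ~central] = 3

    intensity = intensity + rng.normal(0.0, spec.noise_sigma, size=(n, n))
    pixels = np.clip(np.round(intensity), 0, 255).astype(np.uint8)
    return (
        GrayscaleSlice(pixels, pixel_spacing_mm=spec.pixel_spacing_mm, slice_index=slice_index),
        LabelMap(classes),
    )


def _split_sizes(n: int) -> tuple[int, int, int]:
    """Largest-remainder apportionment of n onto the 205/205/206 proportions."""
    total = sum(SPLIT_WEIGHTS)
    exact = [n * w / total for w in SPLIT_WEIGHTS]
    floors = [int(np.floor(e)) for e in exact]
    leftover = n - sum(floors)
    remainders = sorted(
        range(3), key=lambda i: (exact[i] - floors[i], SPLIT_WEIGHTS[i]), reverse=True
    )
    for i in remainders[:leftover]:
        floors[i] += 1
    return tuple(floors)  # type: ignore[return-value]


def generate_dataset(spec: PhantomSpec, n_slices: int, seed: int) -> PhantomDataset:
    """Generate paired slices with a stratified train/val/test split.

    Per-slice seeds derive from the master seed; the split keeps
    lesion-bearing slices proportionally represented in every part.
    """
    if n_slices < 3:
        raise ConfigError(f"need n_slices >= 3, got {n_slices}")
    child_seeds = [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n_slices)]
    slices, truths = [], []
    for i, child in enumerate(child_seeds):
        slc, truth = generate_slice(spec, child, slice_index=i)
        slices.append(slc)
        truths.append(truth)

    sizes = dict(zip(SPLIT_NAMES, _split_sizes(n_slices)))
    has_lesion = np.array([bool((t.classes == 3).any()) for t in truths])
    rng = np.random.default_rng(seed)
    split: dict[str, list[int]] = {name: [] for name in SPLIT_NAMES}
    # deal each stratum out to whichever part has the most relative capacity
    for stratum in (np.nonzero(has_lesion)[0], np.nonzero(~has_lesion)[0]):
        order = rng.permutation(stratum)
        for idx in order:
            name = max(
                SPLIT_NAMES,
                key=lambda s: (sizes[s] - len(split[s])) / sizes[s] if sizes[s] else -1.0,
            )
            split[name].append(int(idx))
    for name in SPLIT_NAMES:
        split[name].sort()
    return PhantomDataset(
        slices=slices, truths=truths, split=split, spec=spec, seed=seed, slice_seeds=child_seeds
    )
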