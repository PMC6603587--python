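import numpy as np
import pytest

from csvd import phantom
from csvd.image_io import GrayscaleSlice, LabelMap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """64x64 phantom spec used throughout the fast tests.

    Pixel-valued knobs are rescaled so the geometry invariants (ring area >
    brain area, lesions fit inside the brain) still hold at this size.
    """
    return phantom.PhantomSpec(
        image_size=64,
        pixel_spacing_mm=1.0,
        skull_thickness_px=8,
        brain_radius_frac=0.28,
        lesion_count_range=(0, 3),
        lesion_diameter_mm_range=(4.0, 10.0),
    )


@pytest.fixture(scope="session")
def small_pair(small_spec):
    """One deterministic (slice, truth) pair that contains lesions."""
    for seed in range(50):
        slc, truth = phantom.generate_slice(small_spec, seed=seed)
        if (truth.classes == 3).any():
            return slc, truth
    raise AssertionError("no lesion-bearing phantom in 50 seeds")


def random_labelmap(rng, height, width):
    return LabelMap(rng.integers(0, 4, size=(height, width)))


def flood_fill_components(mask, connectivity):
    """Brute-force flood-fill labeling oracle (independent of scipy)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int64)
    if connectivity == 4:
        neighbors = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neighbors = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    current = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and labels[r, c] == 0:
                current += 1
                stack = [(r, c)]
                labels[r, c] = current
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in neighbors:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and labels[nr, nc] == 0:
                            labels[nr, nc] = current
                            stack.append((nr, nc))
    return labels, current


def flood_fill_components_3d(stack_mask):
    """26-connected 3D flood-fill oracle."""
    mask = np.asarray(stack_mask, dtype=bool)
    d, h, w = mask.shape
    labels = np.zeros((d, h, w), dtype=np.int64)
    neighbors = [
        (dz, dr, dc)
        for dz in (-1, 0, 1)
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dz, dr, dc) != (0, 0, 0)
    ]
    current = 0
    for z in range(d):
        for r in range(h):
            for c in range(w):
                if mask[z, r, c] and labels[z, r, c] == 0:
                    current += 1
                    todo = [(z, r, c)]
                    labels[z, r, c] = current
                    while todo:
                        zz, rr, cc = todo.pop()
                        for dz, dr, dc in neighbors:
                            nz, nr, nc = zz + dz, rr + dr, cc + dc
                            if (
                                0 <= nz < d
                                and 0 <= nr < h
                                and 0 <= nc < w
                                and mask[nz, nr, nc]
                                and labels[nz, nr, nc] == 0
                            ):
                                labels[nz, nr, nc] = current
                                todo.append((nz, nr, nc))
    return labels, current


def partitions_equal(labels_a, count_a, labels_b, count_b):
    """Two labelings describe the same partition (ids may differ)."""
    if count_a != count_b:
        return False
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if not np.array_equal(a > 0, b > 0):
        return False
    pairs = set(zip(a[a > 0].ravel(), b[b > 0].ravel()))
    return len(pairs) == count_a == len({p[0] for p in pairs}) == len({p[1] for p in pairs})
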