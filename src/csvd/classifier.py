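"""Patch classifiers: a 7-layer CNN and an MLP baseline, 4-way softmax output.

Both operate on 7x7 grayscale patches rescaled to [0, 1] and are trained with
seeded SGD + momentum on a cross-entropy objective, CPU-only and fully
deterministic given the seed.

Layer specs are lists of descriptors::

    ("conv", filters, kernel)   same-padded square convolution + ReLU
    ("pool", kernel)            max-downsampling
    ("dense", units)            fully connected (+ ReLU except for the head)

The default CNN — conv16 -> conv32 -> pool2 -> conv64 -> dense128 ->
dense64 -> dense4 — counts 7 weighted/pooling layers; the MLP flattens the
49 input pixels through dense 128 -> 64 -> 4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _nn
from .brain_extraction import BrainRegion
from .errors import ConfigError, DegenerateDataError, ShapeError
from .image_io import GrayscaleSlice, LabelMap, N_CLASSES
from .patching import PatchGrid, PatchSet, extract_patches, reassemble

__all__ = [
    "ClassifierConfig",
    "PatchClassifier",
    "DEFAULT_CNN_SPEC",
    "DEFAULT_MLP_SPEC",
    "build",
    "train",
    "predict_patches",
    "segment_slice",
    "save_model",
    "load_model",
]

DEFAULT_CNN_SPEC: list[tuple] = [
    ("conv", 16, 3),
    ("conv", 32, 3),
    ("pool", 2),
    ("conv", 64, 3),
    ("dense", 128),
    ("dense", 64),
    ("dense", 4),
]

DEFAULT_MLP_SPEC: list[tuple] = [("dense", 128), ("dense", 64), ("dense", 4)]

#: patch intensities are divided by this before entering the network
INPUT_SCALE = 255.0


@dataclass
class ClassifierConfig:
    kind: str = "cnn"
    layer_spec: list[tuple] = field(default_factory=list)
    epochs: int = 180
    batch_size: int = 128
    learning_rate: float = 0.01
    momentum: float = 0.9
    seed: int = 0
    class_count: int = N_CLASSES
    input_size: int = 7
    class_weighting: bool = False  # inverse-frequency loss weights, off by default
    dtype: str = "float32"  # float64 available for e.g. numeric gradient checks

    def __post_init__(self) -> None:
        if self.kind not in ("cnn", "mlp"):
            raise ConfigError(f"kind must be 'cnn' or 'mlp', got {self.kind!r}")
        if not self.layer_spec:
            self.layer_spec = list(DEFAULT_CNN_SPEC if self.kind == "cnn" else DEFAULT_MLP_SPEC)
        self.layer_spec = [tuple(item) for item in self.layer_spec]
        self._validate_spec()

    def _validate_spec(self) -> None:
        if self.dtype not in ("float32", "float64"):
            raise ConfigError(f"dtype must be float32 or float64, got {self.dtype!r}")
        kinds = [item[0] for item in self.layer_spec]
        unknown = set(kinds) - {"conv", "pool", "dense"}
        if unknown:
            raise ConfigError(f"unknown layer kinds {sorted(unknown)}")
        if self.layer_spec[-1] != ("dense", self.class_count):
            raise ConfigError(f"final layer must be ('dense', {self.class_count})")
        if self.kind == "cnn":
            if "conv" not in kinds or "pool" not in kinds or "dense" not in kinds:
                raise ConfigError("cnn spec needs >= 1 conv, >= 1 pool and >= 1 dense layer")
            if len(self.layer_spec) != 7:
                raise ConfigError(
                    f"cnn spec must total 7 weighted/pooling layers, got {len(self.layer_spec)}"
                )
        else:
            if kinds != ["dense"] * len(kinds):
                raise ConfigError("mlp spec may contain only dense layers")
        if any(k == "conv" for k in kinds) and kinds.index("dense") < len(kinds) - kinds[::-1].index(
            "conv"
        ):
            raise ConfigError("dense layers must come after all conv/pool layers")


def _build_network(config: ClassifierConfig, rng: np.random.Generator) -> _nn.Network:
    layers: list[_nn.Layer] = []
    dtype = np.dtype(config.dtype)
    size = config.input_size
    channels = 1
    flattened = False
    n_dense = sum(1 for item in config.layer_spec if item[0] == "dense")
    dense_seen = 0
    for item in config.layer_spec:
        if item[0] == "conv":
            _, filters, kernel = item
            layers.append(_nn.Conv2D(channels, filters, kernel, rng, dtype=dtype))
            layers.append(_nn.ReLU())
            channels = filters
        elif item[0] == "pool":
            layers.append(_nn.MaxPool2D(item[1]))
            size = size // item[1]
            if size < 1:
                raise ConfigError("pooling shrank the feature map below 1x1")
        else:
            if not flattened:
                layers.append(_nn.Flatten())
                flattened = True
                width = channels * size * size if config.kind == "cnn" else size * size
            layers.append(_nn.Dense(width, item[1], rng, dtype=dtype))
            dense_seen += 1
            if dense_seen < n_dense:
                layers.append(_nn.ReLU())
            width = item[1]
    return _nn.Network(layers)


@dataclass
class PatchClassifier:
    """A (possibly trained) patch classifier; prediction is a pure function."""

    config: ClassifierConfig
    network: _nn.Network
    training_log: list[dict] = field(default_factory=list)
    trained: bool = False

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p, _ in self.network.parameters()))

    def _prepare(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches, dtype=np.float64)
        expected = (self.config.input_size, self.config.input_size)
        if patches.ndim != 3 or patches.shape[1:] != expected:
            raise ShapeError(f"expected (n, {expected[0]}, {expected[1]}) patches, got {patches.shape}")
        x = (patches / INPUT_SCALE).astype(self.config.dtype)
        return x[:, :, :, None]  # NHWC, single channel

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        logits = self.network.forward(self._prepare(patches))
        return _nn.softmax(logits)


def build(config: ClassifierConfig) -> PatchClassifier:
    """Instantiate an untrained classifier with seed-determined weights."""
    rng = np.random.default_rng(config.seed)
    return PatchClassifier(config=config, network=_build_network(config, rng))


def _class_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    return float((pred == truth).mean()) if len(truth) else float("nan")


def train(
    model: PatchClassifier,
    patches: PatchSet,
    val: PatchSet | None = None,
    epochs: int | None = None,
) -> PatchClassifier:
    """Seeded SGD training; runs exactly ``epochs`` full passes.

    The per-epoch log records loss and train/val accuracy.  Raises
    :class:`DegenerateDataError` when fewer than two classes are present.
    """
    if patches.labels is None:
        raise DegenerateDataError("training patches carry no labels")
    y = np.asarray(patches.labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("training set contains a single class")
    cfg = model.config
    n_epochs = cfg.epochs if epochs is None else epochs
    x = model._prepare(patches.patches)
    rng = np.random.default_rng(cfg.seed + 1)  # shuffling stream, distinct from init
    optimizer = _nn.SGDMomentum(model.network, cfg.learning_rate, cfg.momentum)

    weights = None
    if cfg.class_weighting:
        freq = np.bincount(y, minlength=cfg.class_count).astype(np.float64)
        present = freq > 0
        per_class = np.zeros_like(freq)
        per_class[present] = len(y) / (present.sum() * freq[present])
        weights = per_class[y]

    n = len(y)
    for epoch in range(n_epochs):
        order = rng.permutation(n)
        losses = []
        hits = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs = _nn.softmax(model.network.forward(x[idx]))
            loss, grad = _nn.cross_entropy_with_grad(
                probs, y[idx], None if weights is None else weights[idx]
            )
            model.network.backward(grad)
            optimizer.step()
            losses.append(loss)
            hits += int((np.argmax(probs, axis=1) == y[idx]).sum())
        # running accuracy over the epoch's batches (pre-update per batch)
        entry = {"epoch": epoch, "loss": float(np.mean(losses)), "train_accuracy": hits / n}
        if val is not None and val.labels is not None:
            val_pred = predict_patches(model, val, _check_trained=False)[1]
            entry["val_accuracy"] = _class_accuracy(val_pred, np.asarray(val.labels))
        model.training_log.append(entry)
    model.trained = True
    return model


def predict_patches(
    model: PatchClassifier, patches: PatchSet | np.ndarray, _check_trained: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patch probability vectors and argmax classes.

    Probabilities sum to 1 within 1e-6; argmax ties break toward the higher
    class id so a lesion never loses a dead heat.
    """
    if _check_trained and not model.trained:
        raise ConfigError("model has not been trained")
    arr = patches.patches if isinstance(patches, PatchSet) else np.asarray(patches)
    probs = np.empty((len(arr), model.config.class_count))
    chunk = 4096  # bound im2col memory on big slices
    for start in range(0, len(arr), chunk):
        probs[start : start + chunk] = model.predict_proba(arr[start : start + chunk])
    classes = (model.config.class_count - 1) - np.argmax(probs[:, ::-1], axis=1)
    return probs, classes.astype(np.int64)


def segment_slice(
    model: PatchClassifier,
    slc: GrayscaleSlice,
    brain: BrainRegion | None,
    grid: PatchGrid,
) -> LabelMap:
    """Classify brain-overlapping patches and reassemble a full label map.

    Patches whose footprint misses the brain mask entirely are assigned
    class 0 without running inference.
    """
    patchset = extract_patches(slc, grid)
    labels = np.zeros(grid.n_patches, dtype=np.int64)
    if brain is not None:
        mask_patches = extract_patches(brain.mask.astype(np.uint8), grid).patches
        active = mask_patches.reshape(grid.n_patches, -1).any(axis=1)
    else:
        active = np.ones(grid.n_patches, dtype=bool)
    if active.any():
        subset = PatchSet(
            patches=patchset.patches[active],
            positions=[p for p, a in zip(patchset.positions, active) if a],
            grid=grid,
        )
        _, classes = predict_patches(model, subset)
        labels[active] = classes
    return reassemble(labels, grid)


def save_model(model: PatchClassifier, path: str) -> None:
    """Self-describing .npz: config JSON + every weight array + training log."""
    arrays = {
        f"param_{i}": p for i, (p, _) in enumerate(model.network.parameters())
    }
    meta = {
        "config": asdict(model.config),
        "trained": model.trained,
        "training_log": model.training_log,
        "format_version": 1,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str) -> PatchClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_dict = meta["config"]
        cfg_dict["layer_spec"] = [tuple(item) for item in cfg_dict["layer_spec"]]
        config = ClassifierConfig(**cfg_dict)
        model = build(config)
        for i, (p, _) in enumerate(model.network.parameters()):
            p[...] = data[f"param_{i}"]
    model.trained = bool(meta["trained"])
    model.training_log = meta["training_log"]
    return model
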