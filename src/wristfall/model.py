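"""Classifier architectures: specification, construction, training, inference
and on-disk serialization.

Two variants are supported, differing only in the depth of the dense head:

* ``baseline``:  LSTM(U) -> Dense(U, relu) -> BatchNorm -> Dense(1, sigmoid)
* ``improved``:  LSTM(U) -> Dense(U, relu) -> BatchNorm -> Dense(U, relu)
  -> BatchNorm -> Dense(1, sigmoid)

``U`` defaults to the number of samples a device senses per second.  Parameter
totals include the batch-norm running statistics, matching how frameworks
report them: at U=50 the baseline has 13,601 parameters and the improved model
16,351.
"""
from __future__ import annotations

import copy
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._net import LSTM, Adam, BatchNorm, Dense, binary_cross_entropy, sigmoid
from .errors import IntegrityError
from .windowing import Block, blocks_to_arrays

__all__ = [
    "ModelSpec",
    "Model",
    "count_params",
    "build",
    "train",
    "predict_blocks",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

VARIANTS = ("baseline", "improved")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description: unit count, variant and input channel count."""

    units: int
    variant: str = "improved"
    input_channels: int = 3

    def __post_init__(self) -> None:
        if self.units < 1:
            raise ValueError("units must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.input_channels < 1:
            raise ValueError("input_channels must be >= 1")

    def layer_defs(self) -> list[tuple]:
        """Ordered layer descriptors ``(kind, n_in, n_out)``."""
        U, C = self.units, self.input_channels
        defs = [("lstm", C, U), ("dense_relu", U, U), ("norm", U, U)]
        if self.variant == "improved":
            defs += [("dense_relu", U, U), ("norm", U, U)]
        defs.append(("dense_sigmoid", U, 1))
        return defs


def count_params(spec: ModelSpec) -> int:
    """Total parameter count, including batch-norm running statistics.

    Per layer: LSTM contributes ``4*(U*(C+U) + U)``; each Dense(U->U)
    ``U**2 + U``; each norm layer ``4U`` (scale, shift and two running
    statistics); the output Dense(U->1) ``U + 1``.
    """
    total = 0
    for kind, n_in, n_out in spec.layer_defs():
        if kind == "lstm":
            total += 4 * (n_out * (n_in + n_out) + n_out)
        elif kind.startswith("dense"):
            total += n_in * n_out + n_out
        elif kind == "norm":
            total += 4 * n_out
    return total


class Model:
    """A concrete network: spec + layer weights + training provenance."""

    def __init__(self, spec: ModelSpec, layers: list, seed: int, training_meta: dict | None = None):
        self.spec = spec
        self.layers = layers
        self.seed = seed
        self.training_meta = dict(training_meta or {})

    # -- weight access -----------------------------------------------------
    def param_items(self) -> list[tuple[str, np.ndarray]]:
        """All weight arrays in a stable ``layer<idx>.<name>`` order."""
        items = []
        for li, layer in enumerate(self.layers):
            for name in layer.param_names:
                items.append((f"layer{li}.{name}", getattr(layer, name)))
        return items

    def n_params(self) -> int:
        return sum(arr.size for _, arr in self.param_items())

    def copy(self) -> "Model":
        return copy.deepcopy(self)

    @property
    def recurrent_layer(self):
        return self.layers[0]

    # -- inference ---------------------------------------------------------
    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        h = X
        for layer in self.layers:
            h = layer.forward(h, training)
        return sigmoid(h[:, 0])

    def backward(self, dlogit: np.ndarray) -> None:
        d = dlogit
        for layer in reversed(self.layers):
            d = layer.backward(d)


def build(spec: ModelSpec, seed: int = 0) -> Model:
    """Construct a model with seed-reproducible random initialisation."""
    rng = np.random.default_rng(seed)
    layers: list = []
    for kind, n_in, n_out in spec.layer_defs():
        if kind == "lstm":
            layers.append(LSTM(n_in, n_out, rng))
        elif kind == "dense_relu":
            layers.append(Dense(n_in, n_out, "relu", rng))
        elif kind == "dense_sigmoid":
            layers.append(Dense(n_in, n_out, "linear", rng))
        elif kind == "norm":
            layers.append(BatchNorm(n_out))
    return Model(spec, layers, seed, {"seed": seed})


def _as_arrays(blocks) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(blocks, tuple) and len(blocks) == 2:
        X, y = blocks
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_blocks, window, channels)")
        return X, y
    return blocks_to_arrays(list(blocks))


def train(
    model: Model,
    blocks,
    epochs: int = 25,
    batch_size: int = 64,
    seed: int = 0,
    class_weight: str | None = None,
    frozen_layers: frozenset = frozenset(),
    update_bn_stats: bool = True,
) -> Model:
    """Train in place with binary cross-entropy and default Adam.

    ``blocks`` is a sequence of :class:`~wristfall.windowing.Block` (one
    common width required) or a pre-stacked ``(X, y)`` pair.  Training order
    is reshuffled every epoch from ``seed``; per-epoch loss is logged.
    ``frozen_layers`` lists layer indices whose weights must not move.
    """
    X, y = _as_arrays(blocks)
    if X.shape[0] == 0:
        raise ValueError("blocks must be nonempty")
    if X.shape[2] != model.spec.input_channels:
        raise ValueError(
            f"expected {model.spec.input_channels} channels, got {X.shape[2]}"
        )
    if epochs == 0:
        return model
    if y.min() == y.max():
        warnings.warn("training data contains a single class", stacklevel=2)
    weights = None
    if class_weight == "balanced":
        n_pos = max(float(y.sum()), 1.0)
        n_neg = max(float((1 - y).sum()), 1.0)
        w_pos = (n_pos + n_neg) / (2.0 * n_pos)
        w_neg = (n_pos + n_neg) / (2.0 * n_neg)
        weights = np.where(y > 0.5, w_pos, w_neg).astype(np.float32)

    for layer in model.layers:
        if isinstance(layer, BatchNorm):
            layer.update_running = update_bn_stats

    rng = np.random.default_rng(seed)
    adam = Adam()
    n = X.shape[0]
    for epoch in range(epochs):
        perm = rng.permutation(n)
        total_loss = 0.0
        for start in range(0, n, batch_size):
            idx = perm[start : start + batch_size]
            xb, yb = X[idx], y[idx]
            wb = weights[idx] if weights is not None else None
            p = model.forward(xb, training=True)
            total_loss += binary_cross_entropy(p, yb, wb) * len(idx)
            dlogit = (p - yb) / len(idx)
            if wb is not None:
                dlogit = dlogit * wb
            model.backward(dlogit[:, None].astype(np.float32))
            adam.step(model.layers, frozen_layers)
        logger.info("epoch %d/%d loss=%.5f", epoch + 1, epochs, total_loss / n)

    for layer in model.layers:
        if isinstance(layer, BatchNorm):
            layer.update_running = True
    return model


def predict_blocks(model: Model, blocks, batch_size: int = 1024) -> np.ndarray:
    """One probability per block; blocks may be any common sequence length."""
    if isinstance(blocks, np.ndarray):
        X = blocks.astype(np.float32, copy=False)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_blocks, window, channels)")
    else:
        X, _ = _as_arrays(blocks)
    if X.shape[0] == 0:
        return np.empty(0, dtype=np.float64)
    if X.shape[2] != model.spec.input_channels:
        raise ValueError(
            f"expected {model.spec.input_channels} channels, got {X.shape[2]}"
        )
    probs = np.empty(X.shape[0], dtype=np.float64)
    for start in range(0, X.shape[0], batch_size):
        probs[start : start + batch_size] = model.forward(
            X[start : start + batch_size], training=False
        )
    return probs


# -- serialization ---------------------------------------------------------

_MANIFEST_NAME = "manifest.json"
_FORMAT = "wristfall-model/1"


def save_model(model: Model, path) -> Path:
    """Write a model bundle: JSON manifest + per-array little-endian float32."""
    path = Path(path)
    (path / "weights").mkdir(parents=True, exist_ok=True)
    arrays = []
    for index, (name, arr) in enumerate(model.param_items()):
        fname = f"{index:03d}_{name.replace('.', '_')}.bin"
        data = np.ascontiguousarray(arr, dtype="<f4")
        (path / "weights" / fname).write_bytes(data.tobytes())
        arrays.append({"name": name, "file": fname, "shape": list(arr.shape)})
    manifest = {
        "format": _FORMAT,
        "spec": {
            "units": model.spec.units,
            "variant": model.spec.variant,
            "input_channels": model.spec.input_channels,
        },
        "seed": model.seed,
        "training_meta": model.training_meta,
        "arrays": arrays,
    }
    (path / _MANIFEST_NAME).write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return path


def load_model(path) -> Model:
    """Load a bundle written by :func:`save_model`, verifying array shapes."""
    path = Path(path)
    try:
        manifest = json.loads((path / _MANIFEST_NAME).read_text(encoding="utf-8"))
    except FileNotFoundError as exc:
        raise IntegrityError(f"{path}: missing {_MANIFEST_NAME}") from exc
    if manifest.get("format") != _FORMAT:
        raise IntegrityError(f"{path}: unknown bundle format {manifest.get('format')!r}")
    spec = ModelSpec(**manifest["spec"])
    model = build(spec, seed=int(manifest.get("seed", 0)))
    model.training_meta = dict(manifest.get("training_meta", {}))
    entries = manifest["arrays"]
    items = model.param_items()
    if len(entries) != len(items):
        raise IntegrityError(
            f"{path}: manifest lists {len(entries)} arrays, spec requires {len(items)}"
        )
    for entry, (name, arr) in zip(entries, items):
        if entry["name"] != name or tuple(entry["shape"]) != arr.shape:
            raise IntegrityError(
                f"{path}: array {entry['name']!r} does not match spec layout"
            )
        raw = (path / "weights" / entry["file"]).read_bytes()
        expected = int(np.prod(arr.shape)) * 4
        if len(raw) != expected:
            raise IntegrityError(
                f"{path}: {entry['file']} has {len(raw)} bytes, expected {expected}"
            )
        arr[...] = np.frombuffer(raw, dtype="<f4").reshape(arr.shape)
    return model
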