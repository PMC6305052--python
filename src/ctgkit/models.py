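"""Declarative MKNet-A/B/C and MKRNN architectures plus training.

MKNet is a VGG-flavored small CNN for the 120 x 2400 curve raster.  Each
convolution block stacks four 3x3 stride-1 convolutions (the stack has the
same 9x9 receptive field as one 9x9 kernel at lower cost) followed by one
2x2 max pool; blocks use 8, 16 and 32 filters.  MKNet-A is one block +
fc1 + softmax (7 counted layers), MKNet-B adds a second block (12), MKNet-C
a third (17).  Optional per-block 1x1 convolutions, extra dense layers
(fc2/fc3) and dropout are available but off by default.

MKRNN consumes the cleaned trace directly as a (time steps, 1) sequence
through a single LSTM layer.

The layer-counting convention counts conv, pool, dense, softmax and
recurrent layers; dropout and flatten are bookkeeping and are not counted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ctgkit import _engine
from ctgkit.render import AugmentConfig, shift_columns

COUNTED_KINDS = {"conv", "pool", "dense", "softmax", "lstm"}
SEQ_SCALE_LO = 80.0  # sequence inputs scaled (v - 80) / 120 to [0, 1]
SEQ_SCALE_SPAN = 120.0


@dataclass
class LayerSpec:
    kind: str
    kernel: Optional[tuple] = None
    filters: Optional[int] = None
    stride: tuple = (1, 1)
    padding: str = "same"
    units: Optional[int] = None
    rate: Optional[float] = None
    activation: Optional[str] = None
    recurrent_dropout: Optional[float] = None

    def __post_init__(self) -> None:
        allowed = {"conv", "pool", "dense", "dropout", "softmax", "flatten", "lstm"}
        if self.kind not in allowed:
            raise ValueError(f"unknown layer kind {self.kind!r}")


@dataclass
class ModelSpec:
    name: str
    layers: list
    input_shape: tuple
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "input_shape": list(self.input_shape),
            "options": self.options,
            "layers": [dataclasses.asdict(l) for l in self.layers],
        }


@dataclass
class TrainConfig:
    epochs: int = 70
    batch_size: int = 32
    optimizer: str = "rmsprop"
    learning_rate: float = 1e-3
    augmentation: bool = False
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer not in _engine.OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {sorted(_engine.OPTIMIZERS)}")


@dataclass
class TrainedModel:
    spec: ModelSpec
    network: _engine.Network
    history: list  # one dict per epoch: train_acc/train_loss/val_acc/val_loss


def _conv_block(filters: int, with_1x1: bool, dropout_rate: Optional[float]) -> list:
    layers = [
        LayerSpec(kind="conv", kernel=(3, 3), filters=filters, activation="relu")
        for _ in range(4)
    ]
    if with_1x1:
        layers.append(
            LayerSpec(kind="conv", kernel=(1, 1), filters=filters, activation="relu")
        )
    layers.append(LayerSpec(kind="pool", kernel=(2, 2), stride=(2, 2)))
    if dropout_rate:
        layers.append(LayerSpec(kind="dropout", rate=dropout_rate))
    return layers


def build_mknet(
    variant: str,
    with_1x1: bool = False,
    with_fc2: bool = False,
    with_fc3: bool = False,
    dropout_rate: float = 0.0,
    filters: Sequence[int] = (8, 16, 32),
    fc_units: Sequence[int] = (64, 32, 16),
    input_shape: tuple = (120, 2400, 1),
) -> ModelSpec:
    """Construct MKNet-A, -B or -C.

    The conv stacks nest as prefixes: layers(A) ⊂ layers(B) ⊂ layers(C).
    With the default options the counted layer totals are 7, 12 and 17.
    """
    variant = variant.upper().replace("MKNET-", "")
    n_blocks = {"A": 1, "B": 2, "C": 3}.get(variant)
    if n_blocks is None:
        raise ValueError("variant must be A, B or C")
    layers: list[LayerSpec] = []
    for b in range(n_blocks):
        layers += _conv_block(filters[b], with_1x1, dropout_rate or None)
    layers.append(LayerSpec(kind="flatten"))
    layers.append(LayerSpec(kind="dense", units=fc_units[0], activation="relu"))
    if with_fc2:
        layers.append(LayerSpec(kind="dense", units=fc_units[1], activation="relu"))
    if with_fc3:
        layers.append(LayerSpec(kind="dense", units=fc_units[2], activation="relu"))
    layers.append(LayerSpec(kind="softmax", units=2))
    return ModelSpec(
        name=f"MKNet-{variant}",
        layers=layers,
        input_shape=tuple(input_shape),
        options={
            "with_1x1": with_1x1,
            "with_fc2": with_fc2,
            "with_fc3": with_fc3,
            "dropout_rate": dropout_rate,
            "filters": tuple(filters),
        },
    )


def build_mkrnn(
    units: int = 64,
    dropout: float = 0.25,
    recurrent_dropout: float = 0.25,
    time_steps: int = 2400,
) -> ModelSpec:
    """Single-LSTM sequence classifier over (time_steps, 1) inputs."""
    if units < 1:
        raise ValueError("units must be >= 1")
    layers = [
        LayerSpec(kind="lstm", units=units, rate=dropout,
                  recurrent_dropout=recurrent_dropout, activation="tanh"),
        LayerSpec(kind="dense", units=32, activation="relu"),
        LayerSpec(kind="softmax", units=2),
    ]
    return ModelSpec(
        name="MKRNN",
        layers=layers,
        input_shape=(time_steps, 1),
        options={"units": units, "dropout": dropout,
                 "recurrent_dropout": recurrent_dropout},
    )


def count_layers(spec: ModelSpec) -> int:
    """Counted layers: conv + pool + dense + softmax (+ recurrent);
    dropout and flatten are excluded."""
    return sum(1 for l in spec.layers if l.kind in COUNTED_KINDS)


def receptive_field(spec: ModelSpec, upto_layer: Optional[int] = None) -> tuple:
    """Effective receptive field (h, w) of the spatial prefix.

    Standard composition: rf += (k - 1) * jump; jump *= stride, applied per
    axis over conv/pool layers up to ``upto_layer`` (exclusive; defaults to
    the end of the leading spatial stack).
    """
    rf = np.array([1, 1])
    jump = np.array([1, 1])
    layers = spec.layers if upto_layer is None else spec.layers[:upto_layer]
    for l in layers:
        if l.kind in ("conv", "pool"):
            k = np.array(l.kernel)
            s = np.array(l.stride if l.kind == "conv" else l.kernel)
            rf = rf + (k - 1) * jump
            jump = jump * s
        elif upto_layer is not None:
            raise ValueError("non-spatial layer inside the requested range")
        else:
            break
    return (int(rf[0]), int(rf[1]))


def _compile(spec: ModelSpec, rng: np.random.Generator) -> _engine.Network:
    """Instantiate the engine layers for a ModelSpec."""
    layers = []
    if len(spec.input_shape) == 3:
        in_ch = spec.input_shape[2]
        flat_dim = None
        h, w = spec.input_shape[:2]
        for l in spec.layers:
            if l.kind == "conv":
                layers.append(
                    _engine.Conv2D(in_ch, l.filters, l.kernel, stride=l.stride,
                                   padding=l.padding, relu=True, rng=rng)
                )
                if l.padding == "valid":
                    h = (h - l.kernel[0]) // l.stride[0] + 1
                    w = (w - l.kernel[1]) // l.stride[1] + 1
                else:
                    h = -(-h // l.stride[0])
                    w = -(-w // l.stride[1])
                in_ch = l.filters
            elif l.kind == "pool":
                layers.append(_engine.MaxPool2D())
                h, w = h // 2, w // 2
            elif l.kind == "dropout":
                layers.append(_engine.Dropout(l.rate, rng=rng))
            elif l.kind == "flatten":
                layers.append(_engine.Flatten())
                flat_dim = in_ch * h * w
            elif l.kind == "dense":
                layers.append(_engine.Dense(flat_dim, l.units, relu=True, rng=rng))
                flat_dim = l.units
            elif l.kind == "softmax":
                layers.append(_engine.Dense(flat_dim, l.units, relu=False, rng=rng))
    else:  # sequence model
        dim = spec.input_shape[1]
        for l in spec.layers:
            if l.kind == "lstm":
                layers.append(
                    _engine.LSTM(dim, l.units, dropout=l.rate or 0.0,
                                 recurrent_dropout=l.recurrent_dropout or 0.0,
                                 rng=rng)
                )
                dim = l.units
            elif l.kind == "dense":
                layers.append(_engine.Dense(dim, l.units, relu=True, rng=rng))
                dim = l.units
            elif l.kind == "dropout":
                layers.append(_engine.Dropout(l.rate, rng=rng))
            elif l.kind == "softmax":
                layers.append(_engine.Dense(dim, l.units, relu=False, rng=rng))
    return _engine.Network(layers)


def _as_engine_input(spec: ModelSpec, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if len(spec.input_shape) == 3:
        if X.ndim == 3:  # (N, H, W) -> (N, 1, H, W)
            X = X[:, None, :, :]
        elif X.ndim == 4:  # (N, H, W, C) -> (N, C, H, W)
            X = X.transpose(0, 3, 1, 2)
        if X.shape[2] != spec.input_shape[0] or X.shape[3] != spec.input_shape[1]:
            raise ValueError(
                f"input shape {X.shape[2:]} does not match spec "
                f"{spec.input_shape[:2]}"
            )
        return X
    if X.ndim == 2:  # (N, T) -> (N, T, 1)
        X = X[:, :, None]
    if X.shape[1] != spec.input_shape[0]:
        raise ValueError("sequence length does not match spec input shape")
    return X


def scale_sequences(traces: np.ndarray) -> np.ndarray:
    """Scale clipped bpm traces to [0, 1] for the recurrent model."""
    return (np.asarray(traces, dtype=float) - SEQ_SCALE_LO) / SEQ_SCALE_SPAN


def train(
    spec: ModelSpec,
    X,
    y,
    cfg: TrainConfig,
    validation: Optional[tuple] = None,
    warm_start: Optional[TrainedModel] = None,
) -> TrainedModel:
    """Minimize softmax cross-entropy with the configured optimizer.

    With augmentation enabled, every image batch is re-drawn each epoch
    with a random bounded horizontal shift.  ``warm_start`` copies
    matching-shape parameters from a previously trained (typically
    shallower) model before training.  Reproducible for a fixed seed.
    """
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    X = _as_engine_input(spec, X)
    net = _compile(spec, rng)
    if warm_start is not None:
        for p_new, p_old in zip(net.params, warm_start.network.params):
            if p_new.shape == p_old.shape:
                p_new[...] = p_old
    opt = _engine.OPTIMIZERS[cfg.optimizer](lr=cfg.learning_rate)

    is_image = len(spec.input_shape) == 3
    if validation is not None:
        Xv = _as_engine_input(spec, validation[0])
        yv = np.asarray(validation[1], dtype=int)

    history = []
    n = len(y)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = X[idx]
            if cfg.augmentation and is_image:
                max_shift = int(cfg.augment.width_shift_fraction * xb.shape[3])
                xb = np.stack(
                    [
                        shift_columns(
                            im[0], int(rng.integers(-max_shift, max_shift + 1))
                        )[None]
                        for im in xb
                    ]
                )
            loss, probs = net.train_step(xb, y[idx])
            opt.step(net.params, net.grads)
            losses.append(loss * len(idx))
            correct += int((probs.argmax(axis=1) == y[idx]).sum())
        entry = {
            "train_loss": float(np.sum(losses) / n),
            "train_acc": correct / n,
            "val_loss": float("nan"),
            "val_acc": float("nan"),
        }
        if validation is not None:
            pv = net.predict_proba(Xv)
            entry["val_loss"] = _engine.cross_entropy(pv, yv)
            entry["val_acc"] = float((pv.argmax(axis=1) == yv).mean())
        history.append(entry)
    return TrainedModel(spec=spec, network=net, history=history)


def predict_proba(model: TrainedModel, X) -> np.ndarray:
    """Class-probability rows (softmax output); rows sum to 1."""
    X = _as_engine_input(model.spec, X)
    return model.network.predict_proba(X)
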