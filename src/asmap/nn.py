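"""Small CNN feature extractor and dense softmax head, in pure numpy.

Architecture: conv(3x3, 32, relu) -> maxpool(2x2) -> dropout(0.25) ->
conv(3x3, 16, relu) -> maxpool(2x2) -> dropout(0.25) -> flatten ->
dense(512, relu) -> dense(512, relu) -> dense(n_classes, softmax).
Convolutions use valid padding; pooling floors odd dimensions. The same
layer kit provides the dense-only head that consumes flat baseline
feature vectors.

Implemented directly on numpy (im2col convolutions, Adam, inverted
dropout) so the package runs on a bare scientific-Python stack; training
is deterministic for a fixed seed on one machine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from asmap.errors import ValidationError

__all__ = [
    "CNNConfig",
    "HeadConfig",
    "TrainConfig",
    "EvalReport",
    "Model",
    "build_model",
    "build_mlp",
    "cnn_flatten_length",
    "train",
    "extract_features",
    "evaluate",
    "stratified_split",
    "group_split",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CNNConfig:
    input_shape: tuple[int, int, int]  # (H, W, K)
    conv1_maps: int = 32
    conv2_maps: int = 16
    kernel: tuple[int, int] = (3, 3)
    pool: tuple[int, int] = (2, 2)
    dropout_rate: float = 0.25
    padding: str = "valid"

    def __post_init__(self) -> None:
        h, w, k = self.input_shape
        if h != w:
            raise ValidationError(f"input must be square (C x C x K), got {self.input_shape}")
        if k < 1:
            raise ValidationError("need at least one input band")
        if self.kernel != (3, 3) or self.pool != (2, 2) or self.padding != "valid":
            raise ValidationError("only kernel (3,3), pool (2,2), valid padding are supported")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if h < 8:
            raise ValidationError(
                f"input side {h} too small: conv2 stage needs side >= 8 under valid padding"
            )


@dataclass(frozen=True)
class HeadConfig:
    output_units: int
    hidden_units: tuple[int, ...] = (512, 512)

    def __post_init__(self) -> None:
        if self.output_units < 2:
            raise ValidationError(f"need >= 2 output classes, got {self.output_units}")
        if any(u < 1 for u in self.hidden_units):
            raise ValidationError("hidden layer sizes must be positive")


@dataclass(frozen=True)
class TrainConfig:
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 50
    validation_fraction: float = 0.2
    early_stop_patience: int = 5


@dataclass
class EvalReport:
    accuracy: float
    per_class_recall: np.ndarray
    confusion: np.ndarray  # rows: true class, cols: predicted
    n_test: int

    def to_dict(self) -> dict:
        return {
            "accuracy": float(self.accuracy),
            "per_class_recall": [float(r) for r in self.per_class_recall],
            "confusion": self.confusion.astype(int).tolist(),
            "n_test": int(self.n_test),
        }


def cnn_flatten_length(side: int, conv2_maps: int = 16) -> int:
    """Closed-form flattened size: two rounds of (side - 2) // 2, squared, times maps."""
    s = (side - 2) // 2
    s = (s - 2) // 2
    if s < 1:
        raise ValidationError(f"input side {side} collapses to nothing under conv+pool")
    return s * s * conv2_maps


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def init_params(self, rng: np.random.Generator) -> None:  # noqa: ARG002
        pass

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None):
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _Conv3x3(_Layer):
    """Valid-padding 3x3 convolution via im2col."""

    def __init__(self, in_ch: int, filters: int) -> None:
        super().__init__()
        self.in_ch = in_ch
        self.filters = filters
        self.W = np.zeros((9 * in_ch, filters))
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def init_params(self, rng: np.random.Generator) -> None:
        fan_in = 9 * self.in_ch
        self.W[...] = rng.standard_normal(self.W.shape) * np.sqrt(2.0 / fan_in)
        self.b[...] = 0.0

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        ho, wo = h - 2, w - 2
        cols = np.empty((n, ho, wo, 9, c), dtype=x.dtype)
        for idx in range(9):
            i, j = divmod(idx, 3)
            cols[:, :, :, idx, :] = x[:, i : i + ho, j : j + wo, :]
        return cols.reshape(n, ho, wo, 9 * c)

    def forward(self, x, training, rng):
        if x.shape[1] < 3 or x.shape[2] < 3:
            raise ValidationError(
                f"conv stage: spatial size {x.shape[1:3]} smaller than 3x3 kernel"
            )
        if x.shape[3] != self.in_ch:
            raise ValidationError(
                f"conv stage expects {self.in_ch} input maps, got {x.shape[3]}"
            )
        cols = self._im2col(x)
        self._cache = (cols, x.shape)
        return cols @ self.W + self.b

    def backward(self, dout):
        cols, x_shape = self._cache
        n, ho, wo, f = dout.shape
        dmat = dout.reshape(-1, f)
        self.grads[0][...] = cols.reshape(-1, 9 * self.in_ch).T @ dmat
        self.grads[1][...] = dmat.sum(axis=0)
        dcols = (dmat @ self.W.T).reshape(n, ho, wo, 9, self.in_ch)
        dx = np.zeros(x_shape, dtype=dout.dtype)
        for idx in range(9):
            i, j = divmod(idx, 3)
            dx[:, i : i + ho, j : j + wo, :] += dcols[:, :, :, idx, :]
        return dx


class _ReLU(_Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _MaxPool2(_Layer):
    """2x2 max pooling, stride 2, odd trailing row/column dropped."""

    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        if ho < 1 or wo < 1:
            raise ValidationError(f"pool stage: spatial size {(h, w)} smaller than 2x2 window")
        xc = x[:, : 2 * ho, : 2 * wo, :]
        xt = xc.reshape(n, ho, 2, wo, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, ho, wo, c, 4)
        self._argmax = xt.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xt, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, ho, wo, c = dout.shape
        dflat = np.zeros((n, ho, wo, c, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        dx_c = (
            dflat.reshape(n, ho, wo, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, 2 * ho, 2 * wo, c)
        )
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, : 2 * ho, : 2 * wo, :] = dx_c
        return dx


class _Dropout(_Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValidationError("dropout in training mode needs an RNG")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class _Flatten(_Layer):
    def forward(self, x, training, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class _Dense(_Layer):
    def __init__(self, in_dim: int, out_dim: int, relu_fan: bool = True) -> None:
        super().__init__()
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.relu_fan = relu_fan
        self.W = np.zeros((in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def init_params(self, rng: np.random.Generator) -> None:
        if self.relu_fan:
            scale = np.sqrt(2.0 / self.in_dim)
        else:
            scale = np.sqrt(1.0 / self.in_dim)
        self.W[...] = rng.standard_normal(self.W.shape) * scale
        self.b[...] = 0.0

    def forward(self, x, training, rng):
        if x.shape[1] != self.in_dim:
            raise ValidationError(
                f"dense stage expects {self.in_dim} inputs, got {x.shape[1]}"
            )
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class Model:
    """A sequential stack of layers ending in class logits."""

    def __init__(
        self,
        layers: list[_Layer],
        input_shape: tuple,
        n_classes: int,
        kind: str,
        flatten_index: int | None = None,
        meta: dict | None = None,
    ) -> None:
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.n_classes = n_classes
        self.kind = kind
        self.flatten_index = flatten_index
        self.meta = meta or {}
        self.trained = False

    def initialize(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.init_params(rng)
        self.trained = False

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.shape[1:] != self.input_shape:
            raise ValidationError(
                f"model expects input shape {self.input_shape}, got {x.shape[1:]}"
            )
        return x

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        upto: int | None = None,
    ) -> np.ndarray:
        out = self._check_input(x)
        stop = len(self.layers) if upto is None else upto + 1
        for layer in self.layers[:stop]:
            out = layer.forward(out, training, rng)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax(self.forward(x, training=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters
        if len(weights) != len(params):
            raise ValidationError("weight list does not match model parameters")
        for p, w in zip(params, weights):
            p[...] = w


def build_model(cnn: CNNConfig, head: HeadConfig) -> Model:
    """CNN feature extractor plus dense softmax head for C x C x K inputs."""
    h, w, k = cnn.input_shape
    flat_len = cnn_flatten_length(h, cnn.conv2_maps)
    layers: list[_Layer] = [
        _Conv3x3(k, cnn.conv1_maps),
        _ReLU(),
        _MaxPool2(),
        _Dropout(cnn.dropout_rate),
        _Conv3x3(cnn.conv1_maps, cnn.conv2_maps),
        _ReLU(),
        _MaxPool2(),
        _Dropout(cnn.dropout_rate),
        _Flatten(),
    ]
    flatten_index = len(layers) - 1
    in_dim = flat_len
    for units in head.hidden_units:
        layers.append(_Dense(in_dim, units))
        layers.append(_ReLU())
        in_dim = units
    layers.append(_Dense(in_dim, head.output_units, relu_fan=False))
    model = Model(
        layers,
        input_shape=cnn.input_shape,
        n_classes=head.output_units,
        kind="cnn",
        flatten_index=flatten_index,
        meta={"cnn": asdict(cnn), "head": _head_dict(head), "flatten_length": flat_len},
    )
    model.initialize(seed=0)
    return model


def build_mlp(input_dim: int, head: HeadConfig) -> Model:
    """Dense softmax head only, for flat baseline feature vectors."""
    if input_dim < 1:
        raise ValidationError("input_dim must be positive")
    layers: list[_Layer] = []
    in_dim = input_dim
    for units in head.hidden_units:
        layers.append(_Dense(in_dim, units))
        layers.append(_ReLU())
        in_dim = units
    layers.append(_Dense(in_dim, head.output_units, relu_fan=False))
    model = Model(
        layers,
        input_shape=(input_dim,),
        n_classes=head.output_units,
        kind="mlp",
        meta={"input_dim": input_dim, "head": _head_dict(head)},
    )
    model.initialize(seed=0)
    return model


def _head_dict(head: HeadConfig) -> dict:
    return {"output_units": head.output_units, "hidden_units": list(head.hidden_units)}


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------------


def stratified_split(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified held-out split; returns (main_idx, held_idx) sorted."""
    if not 0 < fraction < 1:
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    held: list[int] = []
    main: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_held = int(round(fraction * len(idx)))
        n_held = min(max(n_held, 1), len(idx) - 1)
        held.extend(idx[:n_held])
        main.extend(idx[n_held:])
    return np.sort(np.array(main)), np.sort(np.array(held))


def group_split(
    groups: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out split at group granularity (e.g. simulated subject)."""
    uniq = rng.permutation(np.unique(groups))
    n_held = max(1, int(round(fraction * len(uniq))))
    if n_held >= len(uniq):
        raise ValidationError("cannot hold out every group")
    held_groups = set(uniq[:n_held].tolist())
    mask = np.array([g in held_groups for g in groups])
    return np.flatnonzero(~mask), np.flatnonzero(mask)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g**2
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


def train(model: Model, x: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> dict:
    """Fit with Adam, early stopping on validation loss, best weights restored.

    Returns a history dict with per-epoch train/validation loss and
    accuracy plus the split indices (reproducible from ``cfg.seed``).
    """
    x = model._check_input(x)
    y = np.asarray(y, dtype=np.int64)
    if len(x) != len(y):
        raise ValidationError(f"{len(x)} examples but {len(y)} labels")
    if y.min() < 0 or y.max() >= model.n_classes:
        raise ValidationError(
            f"labels outside [0, {model.n_classes}): saw classes {np.unique(y).tolist()}"
        )
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        small = classes[counts < 2].tolist()
        raise ValidationError(f"classes {small} have fewer than 2 examples")

    rng = np.random.default_rng(cfg.seed)
    model.initialize(seed=cfg.seed)
    train_idx, val_idx = stratified_split(y, cfg.validation_fraction, rng)
    x_tr, y_tr = x[train_idx], y[train_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    opt = _Adam(model.parameters, cfg.learning_rate)
    history: dict = {
        "train_loss": [],
        "train_accuracy": [],
        "val_loss": [],
        "val_accuracy": [],
        "train_indices": train_idx.tolist(),
        "val_indices": val_idx.tolist(),
    }
    best_loss = np.inf
    best_weights = model.get_weights()
    best_epoch = -1
    patience_left = cfg.early_stop_patience

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        ep_loss = 0.0
        ep_correct = 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            xb, yb = x_tr[batch], y_tr[batch]
            logits = model.forward(xb, training=True, rng=rng)
            probs = _softmax(logits)
            ep_loss += _cross_entropy(probs, yb) * len(batch)
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            model.backward(dlogits)
            opt.step(model.gradients)

        val_probs = model.predict_proba(x_val)
        val_loss = _cross_entropy(val_probs, y_val)
        history["train_loss"].append(ep_loss / len(x_tr))
        history["train_accuracy"].append(ep_correct / len(x_tr))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(float((val_probs.argmax(axis=1) == y_val).mean()))

        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
            patience_left = cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    model.set_weights(best_weights)
    model.trained = True
    history["best_epoch"] = best_epoch
    return history


def extract_features(model: Model, x: np.ndarray) -> np.ndarray:
    """Output of the flatten stage, one row per example (inference mode)."""
    if model.flatten_index is None:
        raise ValidationError("model has no flatten stage (dense-only head)")
    return model.forward(x, training=False, upto=model.flatten_index)


def evaluate(model: Model, x: np.ndarray, y: np.ndarray) -> EvalReport:
    """Accuracy, per-class recall, and confusion matrix on a test set."""
    y = np.asarray(y, dtype=np.int64)
    if len(x) == 0:
        raise ValidationError("empty test set")
    if len(x) != len(y):
        raise ValidationError(f"{len(x)} examples but {len(y)} labels")
    pred = model.predict(x)
    n = model.n_classes
    confusion = np.zeros((n, n), dtype=np.int64)
    np.add.at(confusion, (y, pred), 1)
    row_sums = confusion.sum(axis=1)
    with np.errstate(invalid="ignore"):
        recall = np.where(row_sums > 0, np.diag(confusion) / np.maximum(row_sums, 1), np.nan)
    return EvalReport(
        accuracy=float(np.trace(confusion) / len(y)),
        per_class_recall=recall,
        confusion=confusion,
        n_test=len(y),
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(model: Model, path: str | Path) -> None:
    """Write weights (npz) plus a JSON sidecar describing the architecture."""
    path = Path(path)
    arrays = {f"param_{i}": p for i, p in enumerate(model.parameters)}
    np.savez(path.with_suffix(".npz"), **arrays)
    manifest = {
        "kind": model.kind,
        "input_shape": list(model.input_shape),
        "n_classes": model.n_classes,
        "meta": model.meta,
        "trained": model.trained,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_model(path: str | Path) -> Model:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    head = HeadConfig(
        output_units=manifest["meta"]["head"]["output_units"],
        hidden_units=tuple(manifest["meta"]["head"]["hidden_units"]),
    )
    if manifest["kind"] == "cnn":
        cnn_meta = dict(manifest["meta"]["cnn"])
        cnn_meta["input_shape"] = tuple(cnn_meta["input_shape"])
        cnn_meta["kernel"] = tuple(cnn_meta["kernel"])
        cnn_meta["pool"] = tuple(cnn_meta["pool"])
        model = build_model(CNNConfig(**cnn_meta), head)
    else:
        model = build_mlp(manifest["meta"]["input_dim"], head)
    with np.load(path.with_suffix(".npz")) as data:
        model.set_weights([data[f"param_{i}"] for i in range(len(model.parameters))])
    model.trained = bool(manifest["trained"])
    return model
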