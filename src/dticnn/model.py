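"""The 3-hidden-layer 3D CNN classifier.

Architecture: three cascaded hidden layers (3x3x3 SAME convolution ->
batch normalization -> ReLU -> 2x2x2 ceil-mode max pooling) with 32, 64
and 128 feature maps, followed by a single linear map to two logits and
a softmax.  Trained with Adam on the batch-summed softmax cross entropy.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import DomainError, TrainingError

CHANNELS = (32, 64, 128)
N_CLASSES = 2


@dataclass
class TrainingConfig:
    """Optimizer and initialization hyperparameters.

    Reference defaults: Adam with alpha=0.001,
    beta1=0.9, beta2=0.999, eps=1e-8, mini-batches of 45, kernel
    weights from a truncated normal with sd 0.1.
    """

    batch_size: int = 45
    learning_rate: float = 0.001
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    init_sd: float = 0.1
    epochs: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise DomainError("batch_size must be >= 1")
        for name in ("learning_rate", "adam_beta1", "adam_beta2", "adam_epsilon", "init_sd"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.epochs < 1:
            raise DomainError("epochs must be >= 1")


@dataclass
class PCNNArchitecture:
    input_shape: tuple  # (d, w, h, c) with c == 1
    channels: tuple = CHANNELS
    pool_flags: tuple = (True, True, True)
    hidden_spatial: list = field(default_factory=list)  # post-pool shape per hidden layer
    linear_in: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_shape": list(self.input_shape),
                "channels": list(self.channels),
                "pool_flags": list(self.pool_flags),
                "hidden_spatial": [list(s) for s in self.hidden_spatial],
                "linear_in": self.linear_in,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "PCNNArchitecture":
        d = json.loads(s)
        return cls(
            input_shape=tuple(d["input_shape"]),
            channels=tuple(d["channels"]),
            pool_flags=tuple(d["pool_flags"]),
            hidden_spatial=[tuple(x) for x in d["hidden_spatial"]],
            linear_in=d["linear_in"],
        )


def propagate_shapes(input_shape, pool_flags=(True, True, True)):
    """Spatial shape after each hidden layer (SAME conv keeps dims; ceil pool halves)."""
    spatial = tuple(input_shape[:3])
    out = []
    for i, pooled in enumerate(pool_flags):
        if pooled:
            spatial = nn.MaxPool3d.out_shape(spatial)
        if min(spatial) < 1:
            raise DomainError(f"input {input_shape} collapses to {spatial} at hidden layer {i + 1}")
        out.append(spatial)
    return out


class PCNNModel:
    """Stacked layers plus bookkeeping for feature-map extraction."""

    def __init__(self, architecture: PCNNArchitecture, config: TrainingConfig):
        self.architecture = architecture
        self.config = config
        rng = np.random.default_rng(config.seed)
        c_in = architecture.input_shape[3]
        self.layers = []
        self._hidden_ends = []  # layer-stack index after each hidden layer
        for i, (c_out, pooled) in enumerate(zip(architecture.channels, architecture.pool_flags)):
            self.layers.append(
                nn.Conv3dSame(c_in, c_out, rng, config.init_sd, skip_input_grad=(i == 0))
            )
            self.layers.append(nn.BatchNorm(c_out))
            self.layers.append(nn.ReLU())
            if pooled:
                self.layers.append(nn.MaxPool3d())
            self._hidden_ends.append(len(self.layers))
            c_in = c_out
        self.layers.append(nn.Flatten())
        self.layers.append(nn.Linear(architecture.linear_in, N_CLASSES, rng, config.init_sd))

    # -- parameter plumbing ------------------------------------------------
    def parameters(self):
        return [p for layer in self.layers for p in layer.params()]

    def gradients(self):
        return [g for layer in self.layers for g in layer.grads()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self):
        state = {f"param_{i}": p.copy() for i, p in enumerate(self.parameters())}
        moments = []
        for layer in self.layers:
            if isinstance(layer, nn.BatchNorm):
                moments.extend([layer.running_mean.copy(), layer.running_var.copy()])
        for i, m in enumerate(moments):
            state[f"moment_{i}"] = m
        return state

    def load_state_dict(self, state):
        for i, p in enumerate(self.parameters()):
            p[...] = state[f"param_{i}"]
        i = 0
        for layer in self.layers:
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean[...] = state[f"moment_{i}"]
                layer.running_var[...] = state[f"moment_{i + 1}"]
                i += 2

    # -- forward / backward ------------------------------------------------
    def _check_batch(self, batch):
        if batch.ndim != 5 or tuple(batch.shape[1:]) != tuple(self.architecture.input_shape):
            raise DomainError(
                f"batch shape {batch.shape} does not match input {self.architecture.input_shape}"
            )

    def forward_logits(self, batch: np.ndarray, training: bool) -> np.ndarray:
        self._check_batch(batch)
        x = np.asarray(batch, dtype=nn.DTYPE)
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dlogits: np.ndarray):
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d


def build_model(input_shape, config: TrainingConfig, n_pools: int = 3) -> PCNNModel:
    """Construct the model for volumes of ``input_shape`` = (d, w, h[, c=1])."""
    if len(input_shape) == 3:
        input_shape = (*input_shape, 1)
    if len(input_shape) != 4 or input_shape[3] != 1:
        raise DomainError(f"input shape must be (d, w, h) or (d, w, h, 1); got {input_shape}")
    if min(input_shape[:3]) < 8:
        raise DomainError(f"each spatial dim must be >= 8; got {input_shape[:3]}")
    if n_pools not in (2, 3):
        raise DomainError("n_pools must be 2 or 3")
    pool_flags = tuple([True] * n_pools + [False] * (3 - n_pools))
    hidden_spatial = propagate_shapes(input_shape, pool_flags)
    linear_in = int(np.prod(hidden_spatial[-1])) * CHANNELS[-1]
    arch = PCNNArchitecture(
        input_shape=tuple(input_shape),
        pool_flags=pool_flags,
        hidden_spatial=hidden_spatial,
        linear_in=linear_in,
    )
    return PCNNModel(arch, config)


def forward(model: PCNNModel, batch: np.ndarray, training: bool = False) -> np.ndarray:
    """Class-probability pairs, one per batch item."""
    return nn.softmax(model.forward_logits(batch, training))


def cross_entropy_cost(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Batch-summed -log p(true class); zero only at perfect one-hot predictions."""
    predictions = np.atleast_2d(np.asarray(predictions, dtype=np.float64))
    labels = np.atleast_2d(np.asarray(labels, dtype=np.float64))
    if len(predictions) != len(labels):
        raise DomainError("predictions and labels differ in length")
    return nn.softmax_cross_entropy_sum(predictions, labels)


@dataclass
class TrainingHistory:
    train_cost: list = field(default_factory=list)  # mean per-sample cost per epoch
    val_accuracy: list = field(default_factory=list)
    best_epoch: int = -1


def train(
    model: PCNNModel,
    train_volumes: np.ndarray,
    train_labels: np.ndarray,
    val_volumes: np.ndarray,
    val_labels: np.ndarray,
    config: TrainingConfig | None = None,
):
    """Adam training with per-epoch seeded shuffling.

    Returns ``(model, history)`` where the model carries the parameter
    snapshot with the highest validation accuracy over all epochs.
    """
    config = config or model.config
    if len(train_volumes) == 0 or len(val_volumes) == 0:
        raise DomainError("train and validation sets must be nonempty")
    nn.configure_malloc()
    tv = _as_batch(train_volumes)
    vv = _as_batch(val_volumes)
    ty = np.asarray(train_labels, dtype=nn.DTYPE)
    rng = np.random.default_rng(config.seed + 0x5EED)
    opt = nn.Adam(
        model.parameters(),
        lr=config.learning_rate,
        beta1=config.adam_beta1,
        beta2=config.adam_beta2,
        eps=config.adam_epsilon,
    )
    history = TrainingHistory()
    best_acc, best_state = -1.0, None
    n = len(tv)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        cost_sum = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = tv[idx], ty[idx]
            logits = model.forward_logits(xb, training=True)
            probs = nn.softmax(logits)
            cost = nn.softmax_cross_entropy_sum(probs, yb)
            if not np.isfinite(cost):
                raise TrainingError(
                    f"non-finite cost at epoch {epoch}, batch starting {start}"
                )
            cost_sum += cost
            # gradient of the per-sample-mean cost wrt logits
            dlogits = (probs - yb).astype(nn.DTYPE) / len(xb)
            model.backward(dlogits)
            opt.step(model.gradients())
        acc = _accuracy_on(model, vv, val_labels, config.batch_size)
        history.train_cost.append(cost_sum / n)
        history.val_accuracy.append(acc)
        if acc > best_acc:
            best_acc = acc
            best_state = copy.deepcopy(model.state_dict())
            history.best_epoch = epoch
    model.load_state_dict(best_state)
    return model, history


def predict(model: PCNNModel, volumes: np.ndarray, batch_size: int = 45) -> np.ndarray:
    """Inference-mode hard class indices (0 or 1)."""
    vv = _as_batch(volumes)
    out = []
    for start in range(0, len(vv), batch_size):
        probs = forward(model, vv[start : start + batch_size], training=False)
        out.append(probs.argmax(axis=1))
    return np.concatenate(out)


def _accuracy_on(model, volumes, labels, batch_size):
    truth = np.asarray(labels).argmax(axis=1)
    return float((predict(model, volumes, batch_size) == truth).mean())


def _as_batch(volumes: np.ndarray) -> np.ndarray:
    v = np.asarray(volumes, dtype=nn.DTYPE)
    if v.ndim == 4:
        v = v[..., None]
    return v


def extract_feature_maps(model: PCNNModel, volume: np.ndarray, layer_index: int):
    """Post-activation, post-pooling feature maps of one hidden layer.

    ``layer_index`` is 1-based; layer 1 yields exactly 32 maps. Runs in
    inference mode (running batch-norm moments).
    """
    if layer_index not in (1, 2, 3):
        raise DomainError(f"layer_index must be 1..3, got {layer_index}")
    v = _as_batch(np.asarray(volume)[None] if np.asarray(volume).ndim == 3 else volume)
    model._check_batch(v)
    x = v.astype(nn.DTYPE)
    for layer in model.layers[: model._hidden_ends[layer_index - 1]]:
        x = layer.forward(x, training=False)
    # (1, d, w, h, c) -> list of c 3D maps
    return [np.ascontiguousarray(x[0, :, :, :, i]) for i in range(x.shape[-1])]


# -- checkpoint I/O --------------------------------------------------------

def save_checkpoint(model: PCNNModel, path):
    state = model.state_dict()
    state["__arch__"] = np.frombuffer(model.architecture.to_json().encode(), dtype=np.uint8)
    state["__config__"] = np.frombuffer(
        json.dumps(vars(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path) -> PCNNModel:
    with np.load(path) as data:
        arch = PCNNArchitecture.from_json(bytes(data["__arch__"]).decode())
        config = TrainingConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = PCNNModel(arch, config)
        model.load_state_dict({k: data[k] for k in data.files if not k.startswith("__")})
    return model
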