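"""Small deterministic feed-forward networks for quality regression.

Three fixed architectures (one per study dataset) regress perceived quality
on the modulator features, trained with mean-absolute-error loss, RMSprop or
Adam, and early stopping.  The networks are implemented directly on numpy:
dense layers, ReLU/ELU/leaky-ReLU/tanh hidden activations, a single linear
output unit, and plain reverse-mode gradients.  Everything is driven by one
integer seed (initialisation, shuffling, validation split), so a run is
bit-reproducible.

Presets (hidden layers / optimiser):

========  ======  ==========================================  =========
name      inputs  hidden layers                                optimiser
========  ======  ==========================================  =========
data1     14      64 ReLU, 64 ELU, 32 ELU, 16 ELU              RMSprop
data2     6       64 ReLU, 64 ReLU, 64 ReLU, 8 ReLU            Adam
data3     6       128 ReLU, 128 ELU, 64 ELU, 64 ELU            Adam
========  ======  ==========================================  =========
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "TrainedModel",
    "NormalizationParams",
    "preset_spec",
    "normalize_features",
    "train",
    "predict",
    "evaluate_mae",
]

ACTIVATIONS = ("relu", "elu", "lrelu", "tanh", "linear")
_LRELU_SLOPE = 0.01


@dataclass(frozen=True)
class LayerSpec:
    units: int
    activation: str

    def __post_init__(self) -> None:
        if self.units < 1:
            raise ValueError("layer needs at least one unit")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and training protocol of one regression network."""

    input_dim: int
    layers: tuple[LayerSpec, ...]
    optimizer: str = "adam"
    loss: str = "mae"
    max_epochs: int = 2000
    patience: int = 50
    validation_fraction: float = 0.1
    batch_size: int = 32
    learning_rate: float = 1e-3
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.layers[-1].units != 1 or self.layers[-1].activation != "linear":
            raise ValueError("final layer must be a single linear unit")
        if self.optimizer not in ("adam", "rmsprop"):
            raise ValueError("optimizer must be 'adam' or 'rmsprop'")
        if self.loss != "mae":
            raise ValueError("only MAE loss is supported")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in [0, 1)")


_PRESETS: dict[str, dict] = {
    "data1": dict(
        input_dim=14,
        hidden=((64, "relu"), (64, "elu"), (32, "elu"), (16, "elu")),
        optimizer="rmsprop",
    ),
    "data2": dict(
        input_dim=6,
        hidden=((64, "relu"), (64, "relu"), (64, "relu"), (8, "relu")),
        optimizer="adam",
    ),
    "data3": dict(
        input_dim=6,
        hidden=((128, "relu"), (128, "elu"), (64, "elu"), (64, "elu")),
        optimizer="adam",
    ),
}


def preset_spec(name: str, input_dim: int | None = None, **overrides) -> NetworkSpec:
    """One of the three study presets.

    ``input_dim`` may be overridden for feature sets whose width differs
    from the published count (e.g. synthetic chemistry with 13 unique
    compound columns); any other :class:`NetworkSpec` field can be
    overridden by keyword.
    """
    try:
        cfg = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    layers = tuple(LayerSpec(u, a) for u, a in cfg["hidden"]) + (LayerSpec(1, "linear"),)
    spec = NetworkSpec(
        input_dim=cfg["input_dim"] if input_dim is None else int(input_dim),
        layers=layers,
        optimizer=cfg["optimizer"],
    )
    return replace(spec, **overrides) if overrides else spec


@dataclass(frozen=True)
class NormalizationParams:
    columns: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray


def normalize_features(
    train: pd.DataFrame, apply_to: Sequence[pd.DataFrame] = ()
) -> tuple[pd.DataFrame, tuple[pd.DataFrame, ...], NormalizationParams]:
    """Z-score every feature using *training* statistics only.

    The same location/scale is applied to every table in ``apply_to`` --
    held-out tables are never scaled by their own statistics.  Constant
    training columns map to zero (scale forced to 1) with a warning.
    """
    if train.empty:
        raise ValueError("training table is empty")
    mu = train.mean(axis=0).to_numpy(dtype=float)
    sd = train.std(axis=0, ddof=0).to_numpy(dtype=float)
    constant = sd == 0
    if constant.any():
        names = [c for c, flag in zip(train.columns, constant) if flag]
        warnings.warn(f"constant feature columns scaled to zero: {names}")
        sd = np.where(constant, 1.0, sd)
    params = NormalizationParams(
        columns=tuple(map(str, train.columns)), mean=mu, scale=sd
    )

    def _apply(tbl: pd.DataFrame) -> pd.DataFrame:
        if list(map(str, tbl.columns)) != list(params.columns):
            raise ValueError("table columns do not match the training features")
        return (tbl - mu) / sd

    return _apply(train), tuple(_apply(t) for t in apply_to), params


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "elu":
        return np.where(z > 0, z, np.expm1(z))
    if name == "lrelu":
        return np.where(z > 0, z, _LRELU_SLOPE * z)
    if name == "tanh":
        return np.tanh(z)
    return z


def _act_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(float)
    if name == "elu":
        return np.where(z > 0, 1.0, a + 1.0)
    if name == "lrelu":
        return np.where(z > 0, 1.0, _LRELU_SLOPE)
    if name == "tanh":
        return 1.0 - a**2
    return np.ones_like(z)


@dataclass
class TrainedModel:
    """Fitted weights plus the training record."""

    spec: NetworkSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    history: pd.DataFrame  # per-epoch train/validation MAE
    stopping_epoch: int
    normalization: NormalizationParams | None = None
    seed: int = 0


def _forward(
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    spec: NetworkSpec,
    x: np.ndarray,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    zs, acts = [], [x]
    a = x
    for W, b, layer in zip(weights, biases, spec.layers):
        z = a @ W + b
        a = _act(layer.activation, z)
        zs.append(z)
        acts.append(a)
    return zs, acts


def _init_params(spec: NetworkSpec, rng: np.random.Generator):
    weights, biases = [], []
    fan_in = spec.input_dim
    for layer in spec.layers:
        # He-style scaling suits the rectifier-family hidden units
        std = np.sqrt(2.0 / fan_in)
        weights.append(rng.normal(0.0, std, size=(fan_in, layer.units)))
        biases.append(np.zeros(layer.units))
        fan_in = layer.units
    return weights, biases


class _Optimizer:
    def __init__(self, kind: str, params: list[np.ndarray], lr: float):
        self.kind = kind
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        eps = 1e-8
        self.t += 1
        if self.kind == "rmsprop":
            rho = 0.9
            for p, g, v in zip(params, grads, self.v):
                v *= rho
                v += (1 - rho) * g * g
                p -= self.lr * g / (np.sqrt(v) + eps)
        else:  # adam
            b1, b2 = 0.9, 0.999
            for i, (p, g) in enumerate(zip(params, grads)):
                self.m[i] = b1 * self.m[i] + (1 - b1) * g
                self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
                mhat = self.m[i] / (1 - b1**self.t)
                vhat = self.v[i] / (1 - b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _mae(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(np.abs(pred - y)))


def train(
    spec: NetworkSpec,
    features: pd.DataFrame | np.ndarray,
    targets: Sequence[float],
    seed: int = 0,
) -> TrainedModel:
    """Fit the network by minibatch gradient descent on MAE.

    A ``validation_fraction`` split of the rows (seeded) is monitored for
    early stopping: training stops when validation MAE has not improved for
    ``patience`` epochs, and the best-epoch weights are restored.  With
    ``validation_fraction=0`` the training MAE is monitored instead.
    Features are expected to be normalised already.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError(f"features {X.shape} do not align with {y.size} targets")
    if X.shape[1] != spec.input_dim:
        raise ValueError(f"spec expects {spec.input_dim} features, got {X.shape[1]}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in features or targets")
    rng = np.random.default_rng(seed)
    weights, biases = _init_params(spec, rng)

    n_val = int(round(spec.validation_fraction * X.shape[0]))
    perm = rng.permutation(X.shape[0])
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    X_tr, y_tr = X[tr_idx], y[tr_idx]
    X_val, y_val = X[val_idx], y[val_idx]

    params = weights + biases
    opt = _Optimizer(spec.optimizer, params, spec.learning_rate)
    L = len(spec.layers)

    best_loss = np.inf
    best_state: tuple[list[np.ndarray], list[np.ndarray]] | None = None
    best_epoch = 0
    history: list[tuple[float, float]] = []
    n_tr = X_tr.shape[0]
    batch = min(spec.batch_size, n_tr)

    for epoch in range(1, spec.max_epochs + 1):
        order = rng.permutation(n_tr) if spec.shuffle else np.arange(n_tr)
        for start in range(0, n_tr, batch):
            idx = order[start : start + batch]
            xb, yb = X_tr[idx], y_tr[idx]
            zs, acts = _forward(weights, biases, spec, xb)
            pred = acts[-1].ravel()
            # MAE subgradient
            delta = (np.sign(pred - yb) / yb.size)[:, None]
            g_w = [np.empty(0)] * L
            g_b = [np.empty(0)] * L
            for layer_i in range(L - 1, -1, -1):
                delta = delta * _act_grad(
                    spec.layers[layer_i].activation, zs[layer_i], acts[layer_i + 1]
                )
                g_w[layer_i] = acts[layer_i].T @ delta
                g_b[layer_i] = delta.sum(axis=0)
                if layer_i > 0:
                    delta = delta @ weights[layer_i].T
            opt.step(weights + biases, g_w + g_b)

        train_mae = _mae(_forward(weights, biases, spec, X_tr)[1][-1].ravel(), y_tr)
        if n_val:
            val_mae = _mae(_forward(weights, biases, spec, X_val)[1][-1].ravel(), y_val)
        else:
            val_mae = train_mae
        history.append((train_mae, val_mae))
        if val_mae < best_loss - 1e-12:
            best_loss = val_mae
            best_epoch = epoch
            best_state = ([W.copy() for W in weights], [b.copy() for b in biases])
        if epoch - best_epoch >= spec.patience:
            break

    if best_state is not None:
        weights, biases = best_state
    stopping_epoch = len(history)
    hist = pd.DataFrame(history, columns=["train_mae", "val_mae"])
    hist.index = pd.RangeIndex(1, stopping_epoch + 1, name="epoch")
    return TrainedModel(
        spec=spec,
        weights=weights,
        biases=biases,
        history=hist,
        stopping_epoch=stopping_epoch,
        seed=int(seed),
    )


def predict(model: TrainedModel, features: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Network output for (already normalised) features."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.spec.input_dim:
        raise ValueError(f"expected (rows, {model.spec.input_dim}) features")
    return _forward(model.weights, model.biases, model.spec, X)[1][-1].ravel()


def evaluate_mae(
    model: TrainedModel,
    features: pd.DataFrame | np.ndarray,
    targets: Sequence[float],
) -> float:
    """Mean absolute prediction error, in rating units."""
    y = np.asarray(targets, dtype=float).ravel()
    pred = predict(model, features)
    if pred.size != y.size:
        raise ValueError(f"{pred.size} predictions vs {y.size} targets")
    return _mae(pred, y)
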