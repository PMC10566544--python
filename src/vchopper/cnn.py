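"""A compact convolutional network for gated-frame classification, in numpy.

Architecture: three blocks of [3x3 convolution -> batch norm -> ReLU -> 2x2
max pool], a flattened fully connected layer with 100 hidden nodes (batch
norm, ReLU, dropout), and a softmax output over the two classes.  Weights are
trained with RMSprop (learning rate 1e-4) on a cross-entropy loss with early
stopping on the validation loss.

Training follows a three-stage schedule: (1) fit on the training split with
early stopping against the validation split; (2) refit on training +
validation for the stage-1 best epoch count and evaluate on the held-out test
split; (3) refit on the whole data set to produce the deployable model.
Everything is seeded, so a fixed seed reproduces identical confusion
matrices on one machine.

Convolutions are im2col matrix products, so the heavy lifting runs through
BLAS; float32 throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .classify import ClassifierMetrics, compute_metrics, preprocess_frame
from .errors import InvalidConfigError
from .simulate import FrameStack

__all__ = ["TrainSpec", "CnnClassifier", "TrainedCnn", "train_cnn", "classify_frames"]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class _Conv3x3:
    """3x3 convolution, stride 1, same padding; im2col + matmul."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (9 * c_in))
        self.w = rng.normal(0.0, scale, (9 * c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        col = self._im2col(x)
        out = col @ self.w + self.b
        if train:
            self._cache = (col, (n, c, h, w))
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        col, (n, c, h, w) = self._cache
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.dw = col.T @ dmat
        self.db = dmat.sum(axis=0)
        # dx = convolution of dout with the spatially flipped, transposed kernel
        w_r = self.w.reshape(c, 3, 3, self.c_out)
        k = w_r[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(self.c_out * 9, c)
        dp = np.pad(
            dout, ((0, 0), (0, 0), (1, 1), (1, 1))
        )
        win = sliding_window_view(dp, (3, 3), axis=(2, 3))
        dcol = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, self.c_out * 9)
        dx = (dcol @ k).reshape(n, h, w, c).transpose(0, 3, 1, 2)
        self._cache = None
        return dx

    def grads(self):
        return [("w", self.dw), ("b", self.db)]


class _BatchNorm:
    """Batch normalization over all axes but the channel axis."""

    def __init__(self, channels: int, axis_channel: int, momentum: float = 0.9):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.ones(channels, dtype=np.float32)
        self.axis_channel = axis_channel
        self.momentum = momentum
        self.eps = 1e-5
        self._updates = 0

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def _shape(self, x: np.ndarray):
        shape = [1] * x.ndim
        shape[self.axis_channel] = x.shape[self.axis_channel]
        return tuple(shape)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(i for i in range(x.ndim) if i != self.axis_channel)
        shp = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            # cumulative average early on, exponential once enough batches
            # have been seen, so inference stats are usable after few updates
            w = max(1.0 - self.momentum, 1.0 / (self._updates + 1))
            self.run_mean = (1 - w) * self.run_mean + w * mean
            self.run_var = (1 - w) * self.run_var + w * var
            self._updates += 1
            xhat = (x - mean.reshape(shp)) / np.sqrt(var.reshape(shp) + self.eps)
            self._cache = (xhat, var, axes, shp)
        else:
            xhat = (x - self.run_mean.reshape(shp)) / np.sqrt(
                self.run_var.reshape(shp) + self.eps
            )
        return self.gamma.reshape(shp) * xhat + self.beta.reshape(shp)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, var, axes, shp = self._cache
        m = dout.size // dout.shape[self.axis_channel]
        self.dgamma = (dout * xhat).sum(axis=axes)
        self.dbeta = dout.sum(axis=axes)
        dxhat = dout * self.gamma.reshape(shp)
        inv_std = 1.0 / np.sqrt(var.reshape(shp) + self.eps)
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shp)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shp)
        ) * inv_std
        self._cache = None
        return dx

    def grads(self):
        return [("gamma", self.dgamma), ("beta", self.dbeta)]


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx

    def params(self):
        return []

    def grads(self):
        return []


class _MaxPool2:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            mask = xr == out[:, :, :, None, :, None]
            count = mask.sum(axis=(3, 5), keepdims=True)
            self._cache = (mask, count, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, count, shape = self._cache
        dr = mask * (dout[:, :, :, None, :, None] / count)
        self._cache = None
        return dr.reshape(shape)

    def params(self):
        return []

    def grads(self):
        return []


class _Flatten:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def params(self):
        return []

    def grads(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [("w", self.dw), ("b", self.db)]


class _Dropout:
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p <= 0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx

    def params(self):
        return []

    def grads(self):
        return []


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainSpec:
    """Hyperparameters of the classifier and its training schedule."""

    input_size: tuple[int, int] = (128, 128)
    conv_filters: tuple[int, ...] = (8, 16, 32)
    hidden_nodes: int = 100
    dropout: float = 0.5
    learning_rate: float = 1e-4
    rho: float = 0.9
    batch_size: int = 32
    max_epochs: int = 6
    patience: int = 3
    min_delta: float = 1e-3
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise InvalidConfigError("train/val/test split must sum to 1")
        if self.learning_rate <= 0:
            raise InvalidConfigError("learning rate must be positive")


class CnnClassifier:
    """The conv-net itself; build with :func:`train_cnn` or :meth:`load`."""

    def __init__(self, spec: TrainSpec, seed: int):
        self.spec = spec
        rng = np.random.default_rng(seed)
        h, w = spec.input_size
        layers: list = []
        c_in = 1
        for c_out in spec.conv_filters:
            layers += [
                _Conv3x3(c_in, c_out, rng),
                _BatchNorm(c_out, axis_channel=1),
                _ReLU(),
                _MaxPool2(),
            ]
            c_in = c_out
            h, w = h // 2, w // 2
        layers += [
            _Flatten(),
            _Dense(c_in * h * w, spec.hidden_nodes, rng),
            _BatchNorm(spec.hidden_nodes, axis_channel=1),
            _ReLU(),
            _Dropout(spec.dropout, rng),
            _Dense(spec.hidden_nodes, 2, rng),
        ]
        self.layers = layers
        self._opt_cache: dict[int, dict[str, np.ndarray]] = {}

    # -- forward / backward -------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def _backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def _rmsprop_step(self) -> None:
        spec = self.spec
        for idx, layer in enumerate(self.layers):
            grads = dict(layer.grads())
            if not grads:
                continue
            cache = self._opt_cache.setdefault(idx, {})
            for name, param in layer.params():
                g = grads[name]
                c = cache.get(name)
                if c is None:
                    c = np.zeros_like(param)
                c *= spec.rho
                c += (1 - spec.rho) * g * g
                cache[name] = c
                param -= spec.learning_rate * g / (np.sqrt(c) + 1e-8)

    def train_batch(self, x: np.ndarray, y: np.ndarray) -> float:
        logits = self._forward(x, train=True)
        probs = _softmax(logits)
        n = len(y)
        loss = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()
        dlogits = probs
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        self._backward(dlogits.astype(np.float32))
        self._rmsprop_step()
        return float(loss)

    # -- inference ----------------------------------------------------------
    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities for (N, H, W) preprocessed images."""
        images = np.asarray(images, dtype=np.float32)
        out = np.empty((len(images), 2), dtype=np.float64)
        for i in range(0, len(images), batch_size):
            x = images[i : i + batch_size][:, None, :, :]
            out[i : i + batch_size] = _softmax(self._forward(x, train=False))
        return out

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1).astype(np.int8)

    def loss(self, images: np.ndarray, labels: np.ndarray, batch_size: int = 64) -> float:
        probs = self.predict_proba(images, batch_size)
        return float(
            -np.log(np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)).mean()
        )

    # -- persistence --------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for idx, layer in enumerate(self.layers):
            for name, param in layer.params():
                state[f"{idx}.{name}"] = param
            if isinstance(layer, _BatchNorm):
                state[f"{idx}.run_mean"] = layer.run_mean
                state[f"{idx}.run_var"] = layer.run_var
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for idx, layer in enumerate(self.layers):
            for name, param in layer.params():
                param[...] = state[f"{idx}.{name}"]
            if isinstance(layer, _BatchNorm):
                layer.run_mean[...] = state[f"{idx}.run_mean"]
                layer.run_var[...] = state[f"{idx}.run_var"]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        spec = self.spec
        meta = {
            "input_size": list(spec.input_size),
            "conv_filters": list(spec.conv_filters),
            "hidden_nodes": spec.hidden_nodes,
            "dropout": spec.dropout,
            "rng_seed": spec.rng_seed,
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **{k: v.copy() for k, v in self.state_arrays().items()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "CnnClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            spec = TrainSpec(
                input_size=tuple(meta["input_size"]),
                conv_filters=tuple(meta["conv_filters"]),
                hidden_nodes=meta["hidden_nodes"],
                dropout=meta["dropout"],
                rng_seed=meta["rng_seed"],
            )
            model = cls(spec, seed=meta["rng_seed"])
            model.load_state({k: data[k] for k in data.files if k != "__meta__"})
        return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainedCnn:
    """Training product: the deployable model and per-stage metrics."""

    model: CnnClassifier
    metrics: ClassifierMetrics  # stage-2 held-out test metrics
    stage_metrics: dict[str, ClassifierMetrics]
    best_epoch: int
    history: dict[str, list[float]] = field(default_factory=dict)


def _fit(
    model: CnnClassifier,
    x_train: np.ndarray,
    y_train: np.ndarray,
    rng: np.random.Generator,
    n_epochs: int,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    patience: int = 5,
    min_delta: float = 1e-4,
) -> tuple[int, list[float]]:
    """SGD epochs; with validation data, early-stop and restore best weights.

    Returns the best (1-based) epoch and the per-epoch validation losses.
    """
    spec = model.spec
    best_loss = np.inf
    best_epoch = n_epochs
    best_state: dict[str, np.ndarray] | None = None
    stall = 0
    val_losses: list[float] = []
    for epoch in range(1, n_epochs + 1):
        order = rng.permutation(len(x_train))
        for i in range(0, len(order), spec.batch_size):
            idx = order[i : i + spec.batch_size]
            model.train_batch(x_train[idx][:, None, :, :], y_train[idx])
        if x_val is None:
            continue
        vl = model.loss(x_val, y_val)
        val_losses.append(vl)
        if vl < best_loss - min_delta:
            best_loss = vl
            best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    if best_state is not None:
        model.load_state(best_state)
    return best_epoch, val_losses


def _as_image_array(images) -> np.ndarray:
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim != 3:
        raise InvalidConfigError("expected an (N, H, W) array of preprocessed images")
    return arr


def train_cnn(images, labels, spec: TrainSpec | None = None) -> TrainedCnn:
    """Train the gated-frame classifier with the three-stage schedule.

    ``images`` is an (N, 128, 128) array of preprocessed grayscale frames in
    [0, 1] (see :func:`vchopper.classify.preprocess_frame`); ``labels`` the
    matching 0/1 classes.  Both classes must be present; balanced classes are
    recommended.
    """
    spec = spec or TrainSpec()
    x = _as_image_array(images)
    y = np.asarray(labels, dtype=np.int64)
    if len(x) != len(y):
        raise InvalidConfigError("images and labels length mismatch")
    classes = np.unique(y)
    if len(classes) < 2:
        raise InvalidConfigError("training requires both classes present")

    seeds = np.random.SeedSequence(spec.rng_seed).spawn(5)
    split_rng = np.random.default_rng(seeds[0])

    # stratified 60/20/20 split
    train_idx, val_idx, test_idx = [], [], []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        split_rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(spec.split[0] * n))
        n_val = int(round(spec.split[1] * n))
        train_idx.append(idx[:n_train])
        val_idx.append(idx[n_train : n_train + n_val])
        test_idx.append(idx[n_train + n_val :])
    train_idx = np.concatenate(train_idx)
    val_idx = np.concatenate(val_idx)
    test_idx = np.concatenate(test_idx)

    # stage 1: train split, early stopping against validation split
    model1 = CnnClassifier(spec, seed=int(seeds[1].generate_state(1)[0] % 2**31))
    rng1 = np.random.default_rng(seeds[2])
    best_epoch, val_losses = _fit(
        model1,
        x[train_idx],
        y[train_idx],
        rng1,
        spec.max_epochs,
        x[val_idx],
        y[val_idx],
        spec.patience,
        spec.min_delta,
    )
    stage1 = compute_metrics(model1.predict(x[val_idx]), y[val_idx])

    # stage 2: train + validation for the stage-1 best epoch count, test eval
    model2 = CnnClassifier(spec, seed=int(seeds[1].generate_state(1)[0] % 2**31))
    rng2 = np.random.default_rng(seeds[3])
    tv_idx = np.concatenate([train_idx, val_idx])
    _fit(model2, x[tv_idx], y[tv_idx], rng2, best_epoch)
    stage2 = compute_metrics(model2.predict(x[test_idx]), y[test_idx])

    # stage 3: whole data set -> deployable model
    model3 = CnnClassifier(spec, seed=int(seeds[1].generate_state(1)[0] % 2**31))
    rng3 = np.random.default_rng(seeds[4])
    _fit(model3, x, y, rng3, best_epoch)
    stage3 = compute_metrics(model3.predict(x), y)

    return TrainedCnn(
        model=model3,
        metrics=stage2,
        stage_metrics={"stage1_val": stage1, "stage2_test": stage2, "stage3_train": stage3},
        best_epoch=best_epoch,
        history={"val_loss": val_losses},
    )


def classify_frames(
    model: CnnClassifier, frames: FrameStack | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame 0/1 labels and class probabilities for a frame stack."""
    raw = frames.frames if isinstance(frames, FrameStack) else np.asarray(frames)
    size = model.spec.input_size
    images = np.stack([preprocess_frame(frame, out_size=size) for frame in raw])
    probs = model.predict_proba(images)
    return probs.argmax(axis=1).astype(np.int8), probs
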