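"""Fully convolutional binary cell classifier, implemented in NumPy.

The network has exactly three convolutional blocks (convolution -> batch
normalization -> ReLU -> dropout), 2x2 max pooling after the first two blocks,
global max pooling after the third, and a two-way softmax head. Because global
max pooling collapses each feature map to a scalar and there is no fully
connected hidden layer, the parameter count is independent of the input
height/width and the network accepts crops of virtually any size — the
property that lets variable-size cell crops be classified without resizing.

Training minimizes sample-weighted two-class cross-entropy with Adam
(lr 0.001, beta1 0.9, beta2 0.999, eps 1e-7) or SGD (lr 0.0001, momentum 0.0),
batches of 8 zero-padded to the largest crop in the batch, and model
checkpointing: the weights from the epoch with the lowest validation loss are
restored after the final epoch. All randomness (initialization, shuffling,
dropout) flows from one seeded generator, so runs are bit-reproducible.

Forward and backward passes are hand-written (im2col convolutions); a numeric
gradient check in the test suite pins their correctness.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from gadnet.dataset import Batch, CellImage, pad_stack


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv2D:
    """3x3 (configurable) same-padding convolution, stride 1, via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (c_in * k * k + c_out * k * k))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(c_out, c_in * k * k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool):
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # cols: (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        out = cols @ self.W.T + self.b
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray):
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, p = self.k, self.k // 2
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.dW = (dyf.T @ cols).astype(np.float32)
        self.db = dyf.sum(axis=0).astype(np.float32)
        dcols = (dyf @ self.W).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w]

    def grads(self):
        return [self.dW, self.db]


class BatchNorm2D:
    """Per-feature-map batch normalization (eps 1e-3, running momentum 0.99)."""

    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.99):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.eps, self.momentum = eps, momentum

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, training, x.shape)
        return (self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]).astype(
            np.float32
        )

    def backward(self, dy: np.ndarray):
        xhat, inv, training, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.dgamma = (dy * xhat).sum(axis=(0, 2, 3)).astype(np.float32)
        self.dbeta = dy.sum(axis=(0, 2, 3)).astype(np.float32)
        if not training:
            return (dy * self.gamma[None, :, None, None] * inv[None, :, None, None]).astype(
                np.float32
            )
        g = self.gamma[None, :, None, None] * inv[None, :, None, None]
        dy_sum = dy.sum(axis=(0, 2, 3))[None, :, None, None]
        dyx_sum = (dy * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (g * (dy - dy_sum / m - xhat * dyx_sum / m)).astype(np.float32)

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray):
        return dy * self._mask

    def grads(self):
        return []


class Dropout:
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray):
        return dy if self._mask is None else dy * self._mask

    def grads(self):
        return []


class MaxPool2x2:
    """2x2 max pooling, stride 2; a spatial axis shorter than 2 is left alone."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool):
        n, c, h, w = x.shape
        ph = 2 if h >= 2 else 1
        pw = 2 if w >= 2 else 1
        h2, w2 = h // ph, w // pw
        xc = x[:, :, : h2 * ph, : w2 * pw]
        xr = xc.reshape(n, c, h2, ph, w2, pw).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h2, w2, ph * pw
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, (ph, pw), (h2, w2))
        return out

    def backward(self, dy: np.ndarray):
        idx, xshape, (ph, pw), (h2, w2) = self._cache
        n, c, h, w = xshape
        dxr = np.zeros((n, c, h2, w2, ph * pw), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        dxc = dxr.reshape(n, c, h2, w2, ph, pw).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h2 * ph, w2 * pw
        )
        dx = np.zeros(xshape, dtype=np.float32)
        dx[:, :, : h2 * ph, : w2 * pw] = dxc
        return dx

    def grads(self):
        return []


class GlobalMaxPool:
    """Collapse each feature map to its maximum -> fixed-length vector."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool):
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        self._idx = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray):
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h * w), dtype=np.float32)
        np.put_along_axis(dflat, self._idx[..., None], dy[..., None], axis=-1)
        return dflat.reshape(self._shape)

    def grads(self):
        return []


class Dense:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (c_in + c_out))
        self.W = rng.uniform(-limit, limit, size=(c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray):
        self.dW = (self._x.T @ dy).astype(np.float32)
        self.db = dy.sum(axis=0).astype(np.float32)
        return dy @ self.W.T

    def grads(self):
        return [self.dW, self.db]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model specification and training configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FcnSpec:
    """Architecture parameters. Exactly three convolutional blocks; no fully
    connected hidden layer (only the two-way softmax projection)."""

    n_input_channels: int
    block_features: tuple[int, int, int] = (16, 32, 64)
    kernel_size: int = 3
    dropout_rate: float = 0.25
    pool_after_blocks: tuple[int, ...] = (1, 2)  # 2x2 pooling after these blocks

    def validate(self) -> None:
        if not (1 <= self.n_input_channels <= 3):
            raise ValueError("n_input_channels must be 1, 2 or 3")
        if len(self.block_features) != 3:
            raise ValueError("the architecture has exactly three convolutional blocks")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"  # "adam" | "sgd"
    learning_rate: float | None = None  # None -> 0.001 (adam) / 0.0001 (sgd)
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    momentum: float = 0.0
    epochs: int = 500
    batch_size: int = 8
    seed: int = 0

    @property
    def lr(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 0.001 if self.optimizer == "adam" else 0.0001

    def validate(self) -> None:
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class TrainHistory:
    """Per-epoch metrics; ``checkpoint_epoch`` is 1-based argmin of val loss."""

    train_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)

    @property
    def checkpoint_epoch(self) -> int:
        return int(np.argmin(self.val_loss)) + 1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "loss": self.train_loss,
                "accuracy": self.train_accuracy,
                "val_loss": self.val_loss,
                "val_accuracy": self.val_accuracy,
            }
        )


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------


class FcnClassifier:
    """Variable-input-size convolutional classifier with a softmax head.

    ``fit`` trains with weighted cross-entropy and restores the checkpoint
    with the lowest validation loss; ``predict`` returns hard labels (ties
    broken toward the negative class) and class probabilities.
    """

    def __init__(self, spec: FcnSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.layers: list = []
        c_in = spec.n_input_channels
        for bi, c_out in enumerate(spec.block_features, start=1):
            self.layers.append(Conv2D(c_in, c_out, spec.kernel_size, self.rng))
            self.layers.append(BatchNorm2D(c_out))
            self.layers.append(ReLU())
            self.layers.append(Dropout(spec.dropout_rate, self.rng))
            if bi in spec.pool_after_blocks:
                self.layers.append(MaxPool2x2())
            c_in = c_out
        self.layers.append(GlobalMaxPool())
        self.head = Dense(c_in, 2, self.rng)
        self.checkpoint_epoch_: int | None = None

    # -- forward / backward --------------------------------------------------

    def forward_array(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Probabilities for a (n, c, h, w) array; rows sum to 1."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.spec.n_input_channels:
            raise ValueError(
                f"expected (n, {self.spec.n_input_channels}, h, w) input, got {x.shape}"
            )
        for layer in self.layers:
            x = layer.forward(x, training)
        logits = self.head.forward(x, training)
        return softmax(logits)

    def _backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def _params(self) -> list[np.ndarray]:
        layers = [l for l in self.layers if l.params()] + [self.head]
        return [p for l in layers for p in l.params()]

    def _trainable(self):
        layers = [l for l in self.layers if l.params()] + [self.head]
        params, grads = [], []
        for l in layers:
            params.extend(l.params())
            grads.extend(l.grads())
        return params, grads

    def n_parameters(self) -> int:
        total = 0
        for l in self.layers:
            total += sum(p.size for p in l.params())
        return total + sum(p.size for p in self.head.params())

    # -- loss ----------------------------------------------------------------

    @staticmethod
    def _loss_and_grad(probs: np.ndarray, labels: np.ndarray, weights: np.ndarray):
        n = probs.shape[0]
        w = weights / weights.sum()
        p_true = np.clip(probs[np.arange(n), labels], 1e-12, None)
        loss = float(-(w * np.log(p_true)).sum())
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits *= w[:, None]
        return loss, dlogits.astype(np.float32)

    def evaluate(self, images: list[CellImage], batch_size: int = 8) -> tuple[float, float]:
        """Unweighted cross-entropy loss and accuracy on a crop list."""
        total_loss, correct, n = 0.0, 0, 0
        for start in range(0, len(images), batch_size):
            batch = pad_stack(images[start : start + batch_size])
            probs = self.forward_array(batch.values, training=False)
            m = len(batch)
            p_true = np.clip(probs[np.arange(m), batch.labels], 1e-12, None)
            total_loss += float(-np.log(p_true).sum())
            correct += int((probs.argmax(axis=1) == batch.labels).sum())
            n += m
        return total_loss / n, correct / n

    # -- training ------------------------------------------------------------

    def fit(
        self,
        train_images: list[CellImage],
        val_images: list[CellImage],
        cfg: TrainConfig,
    ) -> TrainHistory:
        """Train for ``cfg.epochs`` epochs and restore the best checkpoint.

        ``val_images`` drive per-epoch validation loss and the checkpoint
        selection (lowest validation loss wins). Fully deterministic under
        ``cfg.seed``.
        """
        cfg.validate()
        if not train_images or not val_images:
            raise ValueError("training and validation sets must be nonempty")
        labels = {img.label for img in train_images}
        if len(labels) < 2:
            raise ValueError("training set must contain both classes")

        rng = np.random.default_rng(cfg.seed + 1)
        opt_state = None
        history = TrainHistory()
        best_loss, best_params = np.inf, None

        for epoch in range(cfg.epochs):
            order = rng.permutation(len(train_images))
            epoch_loss, epoch_correct, epoch_n, epoch_w = 0.0, 0, 0, 0.0
            for start in range(0, len(order), cfg.batch_size):
                chunk = [train_images[i] for i in order[start : start + cfg.batch_size]]
                batch = pad_stack(chunk)
                probs = self.forward_array(batch.values, training=True)
                loss, dlogits = self._loss_and_grad(probs, batch.labels, batch.weights)
                self._backward(dlogits)
                opt_state = self._update(cfg, opt_state)
                epoch_loss += loss * batch.weights.sum()
                epoch_w += batch.weights.sum()
                epoch_correct += int((probs.argmax(axis=1) == batch.labels).sum())
                epoch_n += len(batch)
            val_loss, val_acc = self.evaluate(val_images, cfg.batch_size)
            history.train_loss.append(epoch_loss / epoch_w)
            history.train_accuracy.append(epoch_correct / epoch_n)
            history.val_loss.append(val_loss)
            history.val_accuracy.append(val_acc)
            if val_loss < best_loss:
                best_loss = val_loss
                best_params = self._snapshot()

        if best_params is not None:
            self._restore(best_params)
        self.checkpoint_epoch_ = history.checkpoint_epoch
        return history

    def _update(self, cfg: TrainConfig, state):
        params, grads = self._trainable()
        if state is None:
            state = {
                "t": 0,
                "m": [np.zeros_like(p) for p in params],
                "v": [np.zeros_like(p) for p in params],
            }
        state["t"] += 1
        t = state["t"]
        if cfg.optimizer == "adam":
            for p, g, m, v in zip(params, grads, state["m"], state["v"]):
                m *= cfg.beta1
                m += (1 - cfg.beta1) * g
                v *= cfg.beta2
                v += (1 - cfg.beta2) * g * g
                mhat = m / (1 - cfg.beta1**t)
                vhat = v / (1 - cfg.beta2**t)
                p -= cfg.lr * mhat / (np.sqrt(vhat) + cfg.epsilon)
        else:  # sgd
            for p, g, m in zip(params, grads, state["m"]):
                m *= cfg.momentum
                m += g
                p -= cfg.lr * m
        return state

    # -- checkpointing -------------------------------------------------------

    def _snapshot(self):
        params = self._params()
        bn_state = [
            (l.running_mean.copy(), l.running_var.copy())
            for l in self.layers
            if isinstance(l, BatchNorm2D)
        ]
        return ([p.copy() for p in params], bn_state)

    def _restore(self, snap) -> None:
        params = self._params()
        for p, saved in zip(params, snap[0]):
            p[...] = saved
        bns = [l for l in self.layers if isinstance(l, BatchNorm2D)]
        for l, (rm, rv) in zip(bns, snap[1]):
            l.running_mean = rm.copy()
            l.running_var = rv.copy()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        params, bn_state = self._snapshot()
        arrays = {f"param_{i}": p for i, p in enumerate(params)}
        for i, (rm, rv) in enumerate(bn_state):
            arrays[f"bn_mean_{i}"] = rm
            arrays[f"bn_var_{i}"] = rv
        np.savez(path.with_suffix(".npz"), **arrays)
        manifest = {
            "spec": {
                "n_input_channels": self.spec.n_input_channels,
                "block_features": list(self.spec.block_features),
                "kernel_size": self.spec.kernel_size,
                "dropout_rate": self.spec.dropout_rate,
                "pool_after_blocks": list(self.spec.pool_after_blocks),
            },
            "seed": self.seed,
            "checkpoint_epoch": self.checkpoint_epoch_,
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FcnClassifier":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        spec = FcnSpec(
            n_input_channels=manifest["spec"]["n_input_channels"],
            block_features=tuple(manifest["spec"]["block_features"]),
            kernel_size=manifest["spec"]["kernel_size"],
            dropout_rate=manifest["spec"]["dropout_rate"],
            pool_after_blocks=tuple(manifest["spec"]["pool_after_blocks"]),
        )
        model = cls(spec, seed=manifest["seed"])
        data = np.load(path.with_suffix(".npz"))
        params = model._params()
        for i, p in enumerate(params):
            p[...] = data[f"param_{i}"]
        bns = [l for l in model.layers if isinstance(l, BatchNorm2D)]
        for i, l in enumerate(bns):
            l.running_mean = data[f"bn_mean_{i}"].copy()
            l.running_var = data[f"bn_var_{i}"].copy()
        model.checkpoint_epoch_ = manifest.get("checkpoint_epoch")
        return model

    # -- inference -----------------------------------------------------------

    def predict_proba(self, images: list[CellImage], batch_size: int = 8) -> np.ndarray:
        out = []
        for start in range(0, len(images), batch_size):
            batch = pad_stack(images[start : start + batch_size])
            out.append(self.forward_array(batch.values, training=False))
        return np.vstack(out)

    def predict(self, images: list[CellImage], batch_size: int = 8):
        """Hard labels (argmax; a 0.5/0.5 tie goes to the negative class) and
        the class-probability matrix."""
        probs = self.predict_proba(images, batch_size)
        labels = probs.argmax(axis=1)  # index 0 = negative wins exact ties
        return labels, probs


# Thin functional aliases mirroring the operation names used elsewhere.


def build_fcn(spec: FcnSpec, seed: int = 0) -> FcnClassifier:
    return FcnClassifier(spec, seed)


def train_fcn(
    model: FcnClassifier,
    train_images: list[CellImage],
    val_images: list[CellImage],
    cfg: TrainConfig,
) -> TrainHistory:
    return model.fit(train_images, val_images, cfg)
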