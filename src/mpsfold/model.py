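"""Convolutional classifier for per-base structural labels.

Maps a d x L pairing-matrix window to a probability triple over the labels
"(", ")" and "." for the window's centre base.  The architecture is a stack
of small convolution blocks (16 3x3 kernels, ReLU, 3x3 max pooling with
stride 2) followed by two 32-node dense layers and a 3-way softmax, trained
with plain mini-batch SGD on the cross-entropy loss from Xavier (Glorot
uniform) initialisation.  Three blocks suit 11 x 120 inputs (single-family
setting); two blocks suit 19 x 128 (general setting).

The network is implemented directly on numpy arrays with explicit forward
and backward passes (gradient-checked in the test suite); given a seed,
configuration and data order, training is bit-for-bit reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .encoding import EncodingConfig, encode_windows
from .structures import Sequence

__all__ = [
    "ConfigMismatchError",
    "ConvNetClassifier",
    "ModelConfig",
    "load_model",
    "predict_probs",
    "train",
    "upsample_balance",
]

logger = logging.getLogger(__name__)

N_LABELS = 3


class ConfigMismatchError(ValueError):
    """Model was trained under a different encoding configuration."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimisation settings.

    conv_blocks       convolution+pool blocks: 3 (single family) or 2 (general).
    kernels_per_conv  filters per convolution (16).
    dense_nodes       width of each of the two fully-connected layers (32).
    batch_size        mini-batch size: 256 (single family) or 512 (general).
    iterations        optimiser steps (not epochs): 400 or 2000.
    learning_rate     SGD step size.
    seed              seeds initialisation and batch order.
    """

    conv_blocks: int = 3
    kernels_per_conv: int = 16
    dense_nodes: int = 32
    batch_size: int = 256
    iterations: int = 400
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_blocks < 1:
            raise ValueError("conv_blocks must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def to_dict(self) -> dict:
        return {
            "conv_blocks": self.conv_blocks,
            "kernels_per_conv": self.kernels_per_conv,
            "dense_nodes": self.dense_nodes,
            "batch_size": self.batch_size,
            "iterations": self.iterations,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
        }


# ---------------------------------------------------------------- layers


class _Conv3x3:
    """3x3 convolution, stride 1, zero same-padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype):
        fan_in, fan_out = c_in * 9, c_out * 9
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.w = rng.uniform(-limit, limit, (c_in * 9, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (n,c,h,w,3,3)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, h, w, c * 9
        )
        if train:
            self._cols, self._shape = cols, (n, c, h, w)
        out = cols @ self.w + self.b
        return out.transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        d2 = dout.transpose(0, 2, 3, 1)  # (n,h,w,c_out)
        self.dw = self._cols.reshape(-1, c * 9).T @ d2.reshape(-1, self.c_out)
        self.db = d2.sum(axis=(0, 1, 2))
        dcols = (d2 @ self.w.T).reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=dout.dtype)
        for r in range(3):
            for s in range(3):
                dxp[:, :, r : r + h, s : s + w] += dcols[:, :, :, :, r, s].transpose(
                    0, 3, 1, 2
                )
        del self._cols
        return dxp[:, :, 1 : h + 1, 1 : w + 1]

    @property
    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    params: dict = {}

    def grads(self):
        return {}


class _MaxPool3x3s2:
    """3x3 max pooling, stride 2, ceil-mode output size ceil(dim / 2)."""

    @staticmethod
    def out_size(dim: int) -> int:
        return (dim + 1) // 2

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = self.out_size(h), self.out_size(w)
        ph, pw = (oh - 1) * 2 + 3 - h, (ow - 1) * 2 + 3 - w
        xp = np.pad(
            x, ((0, 0), (0, 0), (0, ph), (0, pw)), constant_values=-np.inf
        )
        wins = sliding_window_view(xp, (3, 3), axis=(2, 3))[:, :, ::2, ::2]
        flat = wins.reshape(n, c, oh, ow, 9)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._arg, self._in_shape, self._pad = arg, (n, c, h, w), (ph, pw)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        ph, pw = self._pad
        oh, ow = dout.shape[2], dout.shape[3]
        ni, ci, oi, oj = np.indices((n, c, oh, ow), sparse=False)
        rows = 2 * oi + self._arg // 3
        cols = 2 * oj + self._arg % 3
        dxp = np.zeros((n, c, h + ph, w + pw), dtype=dout.dtype)
        np.add.at(dxp, (ni, ci, rows, cols), dout)
        return dxp[:, :, :h, :w]

    params: dict = {}

    def grads(self):
        return {}


class _Flatten:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    params: dict = {}

    def grads(self):
        return {}


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, (n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T

    @property
    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits.astype(np.float64)
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------- network


class ConvNetClassifier:
    """The window -> label-probability network.

    Parameters are created lazily from the first batch's shape (or
    explicitly via :meth:`build`) so one config serves both input sizes.
    """

    def __init__(
        self,
        cfg: ModelConfig = ModelConfig(),
        encoding: EncodingConfig | None = None,
        dtype=np.float32,
    ):
        self.cfg = cfg
        self.encoding = encoding
        self.dtype = dtype
        self.layers: list | None = None
        self.input_shape: tuple[int, int] | None = None
        self.history: list[dict] = []

    # -- architecture

    def build(self, d: int, length: int) -> None:
        rng = np.random.default_rng(self.cfg.seed)
        layers: list = []
        c, h, w = 1, d, length
        for _ in range(self.cfg.conv_blocks):
            layers += [
                _Conv3x3(c, self.cfg.kernels_per_conv, rng, self.dtype),
                _ReLU(),
                _MaxPool3x3s2(),
            ]
            c = self.cfg.kernels_per_conv
            # ceil-mode pooling keeps h, w >= 1 at any depth
            h, w = _MaxPool3x3s2.out_size(h), _MaxPool3x3s2.out_size(w)
        layers.append(_Flatten())
        n_in = c * h * w
        for _ in range(2):
            layers += [_Dense(n_in, self.cfg.dense_nodes, rng, self.dtype), _ReLU()]
            n_in = self.cfg.dense_nodes
        layers.append(_Dense(n_in, N_LABELS, rng, self.dtype))
        self.layers = layers
        self.input_shape = (d, length)
        self._data_rng = rng

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def _backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    # -- training

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        eval_every: int = 25,
    ) -> "ConvNetClassifier":
        """Mini-batch SGD for ``cfg.iterations`` steps over (x, y).

        x: (N, d, L) windows; y: (N,) integer labels in {0, 1, 2}.
        Loss/accuracy on each evaluation batch are appended to ``history``.
        """
        x = np.asarray(x, dtype=self.dtype)
        y = np.asarray(y)
        if x.ndim != 3:
            raise ValueError(f"expected (N, d, L) windows, got shape {x.shape}")
        if len(x) == 0:
            raise ValueError("empty training set")
        if len(x) != len(y):
            raise ValueError("windows and labels differ in length")
        if self.layers is None:
            self.build(x.shape[1], x.shape[2])
        elif self.input_shape != x.shape[1:]:
            raise ValueError(
                f"window shape {x.shape[1:]} != model input {self.input_shape}"
            )
        rng = self._data_rng
        n = len(x)
        order = rng.permutation(n)
        cursor = 0
        lr = self.cfg.learning_rate
        for step in range(1, self.cfg.iterations + 1):
            if cursor + self.cfg.batch_size > n:
                order = rng.permutation(n)
                cursor = 0
            idx = order[cursor : cursor + self.cfg.batch_size]
            cursor += self.cfg.batch_size
            xb = x[idx][:, None, :, :]  # add channel axis
            yb = y[idx]
            logits = self._forward(xb, train=True)
            probs = _softmax(logits)
            loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits = (dlogits / len(yb)).astype(self.dtype)
            self._backward(dlogits)
            for layer in self.layers:
                g = layer.grads()
                for name, grad in g.items():
                    layer.params[name] -= lr * grad
            if step % eval_every == 0 or step == self.cfg.iterations:
                acc = float(np.mean(probs.argmax(axis=1) == yb))
                self.history.append(
                    {"step": step, "loss": float(loss), "accuracy": acc}
                )
        return self

    # -- inference

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Probability triples for (N, d, L) windows; rows sum to 1."""
        if self.layers is None:
            raise RuntimeError("model is not trained/built")
        x = np.asarray(x, dtype=self.dtype)
        out = np.empty((len(x), N_LABELS))
        for start in range(0, len(x), batch_size):
            xb = x[start : start + batch_size][:, None, :, :]
            out[start : start + len(xb)] = _softmax(self._forward(xb, train=False))
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    # -- persistence

    def save(self, path) -> None:
        """Single-file .npz checkpoint with config + encoding sidecar."""
        if self.layers is None:
            raise RuntimeError("nothing to save: model not built")
        arrays = {}
        for k, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                arrays[f"layer{k}_{name}"] = value
        meta = {
            "model": self.cfg.to_dict(),
            "encoding": self.encoding.to_dict() if self.encoding else None,
            "input_shape": list(self.input_shape),
        }
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)


def load_model(path) -> ConvNetClassifier:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        cfg = ModelConfig(**meta["model"])
        enc = EncodingConfig(**meta["encoding"]) if meta["encoding"] else None
        model = ConvNetClassifier(cfg, encoding=enc)
        model.build(*meta["input_shape"])
        for k, layer in enumerate(model.layers):
            for name in layer.params:
                layer.params[name][...] = data[f"layer{k}_{name}"]
    return model


# ---------------------------------------------------------------- helpers


def upsample_balance(
    x: np.ndarray, y: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Equalise class counts by resampling minority classes with replacement.

    All original samples are retained (appended copies only); with a single
    present class the input is returned unchanged with a warning.
    """
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty collection")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) == 1:
        logger.warning("upsample_balance: single class %s, nothing to balance", classes[0])
        return x, y
    target = counts.max()
    rng = np.random.default_rng(seed)
    extra = []
    for cls, cnt in zip(classes, counts):
        if cnt < target:
            pool = np.nonzero(y == cls)[0]
            extra.append(rng.choice(pool, size=target - cnt, replace=True))
    idx = np.concatenate([np.arange(len(y))] + extra)
    return x[idx], y[idx]


def train(
    windows: np.ndarray,
    labels: np.ndarray,
    cfg: ModelConfig = ModelConfig(),
    encoding: EncodingConfig | None = None,
    balance: bool = True,
) -> ConvNetClassifier:
    """Train a classifier on labelled windows (upsampled to class balance)."""
    windows = np.asarray(windows)
    labels = np.asarray(labels)
    if balance and len(labels):
        windows, labels = upsample_balance(windows, labels, seed=cfg.seed)
    model = ConvNetClassifier(cfg, encoding=encoding)
    return model.fit(windows, labels)


def predict_probs(
    model: ConvNetClassifier, seq: Sequence, cfg: EncodingConfig
) -> np.ndarray:
    """Per-base (p_left, p_right, p_point) for a sequence: (n, 3) array.

    The model's stored encoding configuration must match ``cfg`` so windows
    are produced exactly as at training time.
    """
    if model.encoding is not None and model.encoding != cfg:
        raise ConfigMismatchError(
            f"model encoding {model.encoding} != requested {cfg}"
        )
    return model.predict_proba(encode_windows(seq, cfg))
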