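"""Minimal NumPy neural-network engine for small image classifiers.

Implements exactly the pieces the spectrogram classifier needs — 2-D
convolution ("same" padding, stride 1), 2×2 max-pooling, inverted dropout,
dense layers, ReLU, softmax with sparse categorical cross-entropy, and the
RMSprop optimizer — in float32 with the heavy lifting routed through BLAS
matmuls.  Everything is seeded and deterministic: a fixed seed gives
bit-identical initial weights, dropout masks and training trajectories on
one machine.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Conv2D",
    "MaxPool2D",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "RMSprop",
    "softmax",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 "same" convolution with optional ReLU, NHWC layout.

    Implemented as a sum of k² spatially shifted ``(B,H,W,C) @ (C,F)``
    matmuls rather than an explicit im2col patch matrix: the arithmetic is
    identical but the giant patch copy is avoided, which is what dominates
    wall time for large feature maps on one CPU.  ``need_input_grad=False``
    (for the first layer of a network) skips the input-gradient pass.
    """

    def __init__(
        self,
        in_channels: int,
        filters: int,
        kernel_size: int,
        activation: str | None = "relu",
        rng: np.random.Generator | None = None,
        dtype=np.float32,
        need_input_grad: bool = True,
    ) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.filters = filters
        self.k = kernel_size
        self.activation = activation
        self.need_input_grad = need_input_grad
        rng = rng or np.random.default_rng()
        fan_in = kernel_size * kernel_size * in_channels
        fan_out = kernel_size * kernel_size * filters
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.w = rng.uniform(
            -limit, limit, size=(kernel_size, kernel_size, in_channels, filters)
        ).astype(dtype)
        self.b = np.zeros(filters, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))

    @property
    def _use_im2col(self) -> bool:
        # few input channels (the RGB layer): one GEMM on a small patch
        # matrix beats k² accumulation passes over the full output
        return self.k * self.k * self.in_channels <= 256

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, h, w, _ = x.shape
        xp = self._pad(x)
        self._hw = (h, w)
        if self._use_im2col:
            cols = np.concatenate(
                [
                    xp[:, u : u + h, v : v + w, :]
                    for u in range(self.k)
                    for v in range(self.k)
                ],
                axis=-1,
            ).reshape(b * h * w, -1)
            self._cols, self._xp = cols, None
            out = (cols @ self.w.reshape(-1, self.filters) + self.b).reshape(
                b, h, w, self.filters
            )
        else:
            self._cols, self._xp = None, xp
            out = np.empty((b, h, w, self.filters), dtype=x.dtype)
            out[...] = self.b
            for u in range(self.k):
                for v in range(self.k):
                    out += xp[:, u : u + h, v : v + w, :] @ self.w[u, v]
        if self.activation == "relu":
            self._mask = out > 0
            out = np.where(self._mask, out, 0.0)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dout = np.where(self._mask, dout, 0.0)
            self._mask = None
        h, w = self._hw
        self.grads[1][...] = dout.sum(axis=(0, 1, 2))
        if self._cols is not None:
            dflat = dout.reshape(-1, self.filters)
            self.grads[0][...] = (self._cols.T @ dflat).reshape(self.grads[0].shape)
            self._cols = None
            if not self.need_input_grad:
                return dout  # first layer: caller discards this
            # fall through to the shift path for dx only
            dxp = self._pad(np.zeros(dout.shape[:3] + (self.in_channels,), dout.dtype))
            for u in range(self.k):
                for v in range(self.k):
                    dxp[:, u : u + h, v : v + w, :] += dout @ self.w[u, v].T
            p = self.k // 2
            return dxp[:, p : p + h, p : p + w, :]
        xp = self._xp
        dxp = np.zeros_like(xp) if self.need_input_grad else None
        for u in range(self.k):
            for v in range(self.k):
                view = xp[:, u : u + h, v : v + w, :]
                # dW as batched (C,W)@(W,F) products reduced over stacks:
                # avoids materialising a contiguous copy of the view
                prod = np.matmul(view.transpose(0, 1, 3, 2), dout)
                self.grads[0][u, v] = prod.sum(axis=(0, 1))
                if dxp is not None:
                    dxp[:, u : u + h, v : v + w, :] += dout @ self.w[u, v].T
        self._xp = None
        if dxp is None:
            return dout  # first layer: caller discards this
        p = self.k // 2
        return dxp[:, p : p + h, p : p + w, :]


class MaxPool2D(Layer):
    """2×2 max-pooling with stride 2; trailing odd row/column dropped."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._shape = x.shape
        xr = (
            x[:, : h2 * 2, : w2 * 2, :]
            .reshape(b, h2, 2, w2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(b, h2, w2, c, 4)
        )
        self._idx = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((b, h2, w2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._shape, dtype=dout.dtype)
        dx[:, : h2 * 2, : w2 * 2, :] = (
            dxr.reshape(b, h2, w2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(b, h2 * 2, w2 * 2, c)
        )
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(x.dtype) / (
            1.0 - self.rate
        )
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        activation: str | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.activation = activation
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / (in_features + out_features))
        self.w = rng.uniform(-limit, limit, size=(in_features, out_features)).astype(
            dtype
        )
        self.b = np.zeros(out_features, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        out = x @ self.w + self.b
        if self.activation == "relu":
            self._mask = out > 0
            out = np.where(self._mask, out, 0.0)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dout = np.where(self._mask, dout, 0.0)
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx


class RMSprop:
    """RMSprop as used for the classifier: lr 5e-4, rho 0.9, eps 1e-8."""

    def __init__(self, lr: float = 5e-4, rho: float = 0.9, eps: float = 1e-8) -> None:
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._cache: dict[int, np.ndarray] = {}

    def step(self, layers: Sequence[Layer]) -> None:
        for layer in layers:
            for p, g in zip(layer.params, layer.grads):
                key = id(p)
                cache = self._cache.setdefault(key, np.zeros_like(p))
                cache *= self.rho
                cache += (1.0 - self.rho) * g * g
                p -= self.lr * g / (np.sqrt(cache) + self.eps)


class Sequential:
    """A feed-forward stack trained with softmax cross-entropy.

    The final layer must emit class logits; :meth:`predict_proba` applies
    the softmax.  ``loss_and_grad`` fuses softmax and sparse categorical
    cross-entropy for a numerically stable gradient.
    """

    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    @property
    def n_params(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], training=False)))
        return np.concatenate(out, axis=0)

    def loss_and_grad(
        self, x: np.ndarray, y: np.ndarray, training: bool = True
    ) -> tuple[float, np.ndarray]:
        """Mean sparse-categorical cross-entropy and the logit gradient."""
        logits = self.forward(x, training=training)
        p = softmax(logits)
        n = x.shape[0]
        eps = np.finfo(p.dtype).tiny
        loss = -float(np.mean(np.log(p[np.arange(n), y] + eps)))
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        return loss, dlogits

    def train_step(
        self, x: np.ndarray, y: np.ndarray, optimizer: RMSprop
    ) -> float:
        loss, dlogits = self.loss_and_grad(x, y, training=True)
        dout = dlogits
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        optimizer.step(self.layers)
        return loss

    def evaluate_loss_acc(
        self, x: np.ndarray, y: np.ndarray, batch_size: int = 8
    ) -> tuple[float, float]:
        losses, correct = [], 0
        for i in range(0, x.shape[0], batch_size):
            xb, yb = x[i : i + batch_size], y[i : i + batch_size]
            logits = self.forward(xb, training=False)
            p = softmax(logits)
            eps = np.finfo(p.dtype).tiny
            losses.append(
                -np.log(p[np.arange(len(yb)), yb] + eps).sum()
            )
            correct += int((p.argmax(axis=1) == yb).sum())
        return float(np.sum(losses) / x.shape[0]), correct / x.shape[0]

    # -- weight (de)serialisation --------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight count mismatch")
        for p, w in zip(flat, weights):
            p[...] = w

    def save(self, path) -> None:
        np.savez(path, *self.get_weights())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.set_weights([data[k] for k in sorted(data.files, key=lambda s: int(s.split("_")[1]))])
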