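"""Minimal NumPy neural-network layers with explicit backpropagation.

Only what the fixed architecture needs: 1-D convolution (im2col), 2-wide
max pooling, ReLU, global max pooling, dense layers, a numerically stable
sigmoid/binary-cross-entropy head, and Adam. float32 throughout.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> Dict[str, np.ndarray]:
        return {}

    def gradients(self) -> Dict[str, np.ndarray]:
        return {}


class Conv1d(Layer):
    """1-D convolution over (N, C_in, L) inputs; weights (C_out, C_in, K)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1):
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.W = np.zeros((c_out, c_in, kernel), dtype=np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def init_weights(self, rng: np.random.Generator) -> None:
        fan_in = self.c_in * self.kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), self.W.shape).astype(np.float32)
        self.b = np.zeros(self.c_out, dtype=np.float32)

    def out_length(self, l_in: int) -> int:
        return (l_in - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c_in, l_in = x.shape
        l_out = self.out_length(l_in)
        windows = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        windows = windows[:, :, :: self.stride][:, :, :l_out]  # (N, C_in, L_out, K)
        self._cols = (
            windows.transpose(0, 2, 1, 3).reshape(n, l_out, c_in * self.kernel)
        )
        self._l_in = l_in
        w_flat = self.W.reshape(self.c_out, -1)
        out = self._cols @ w_flat.T + self.b  # (N, L_out, C_out)
        return out.transpose(0, 2, 1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, l_out = dout.shape
        d = dout.transpose(0, 2, 1)  # (N, L_out, C_out)
        cols2d = self._cols.reshape(-1, self.c_in * self.kernel)
        d2d = d.reshape(-1, self.c_out)
        self.dW = (d2d.T @ cols2d).reshape(self.W.shape)
        self.db = d2d.sum(axis=0)
        dcols = (d @ self.W.reshape(self.c_out, -1)).reshape(
            n, l_out, self.c_in, self.kernel
        )
        dx = np.zeros((n, self.c_in, self._l_in), dtype=dout.dtype)
        s = self.stride
        for k in range(self.kernel):
            dx[:, :, k : k + s * l_out : s] += dcols[:, :, :, k].transpose(0, 2, 1)
        return dx

    def parameters(self) -> Dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def gradients(self) -> Dict[str, np.ndarray]:
        return {"W": self.dW, "b": self.db}


class MaxPool1d(Layer):
    """Non-overlapping pooling (kernel == stride == 2); trailing element dropped."""

    def __init__(self, kernel: int = 2):
        self.kernel = kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, l_in = x.shape
        l_out = l_in // self.kernel
        xr = x[:, :, : l_out * self.kernel].reshape(n, c, l_out, self.kernel)
        self._argmax = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, l_out = dout.shape
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        ni, ci, li = np.ogrid[:n, :c, :l_out]
        dxr = dx[:, :, : l_out * self.kernel].reshape(n, c, l_out, self.kernel)
        dxr[ni, ci, li, self._argmax] = dout
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class GlobalMaxPool(Layer):
    """(N, C, L) -> (N, C) by max over positions."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._argmax = x.argmax(axis=2)
        self._in_shape = x.shape
        return x.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, _ = self._in_shape
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        ni, ci = np.ogrid[:n, :c]
        dx[ni, ci, self._argmax] = dout
        return dx


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int):
        self.n_in, self.n_out = n_in, n_out
        self.W = np.zeros((n_in, n_out), dtype=np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def init_weights(self, rng: np.random.Generator) -> None:
        self.W = rng.normal(0.0, np.sqrt(2.0 / self.n_in), self.W.shape).astype(
            np.float32
        )
        self.b = np.zeros(self.n_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def parameters(self) -> Dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def gradients(self) -> Dict[str, np.ndarray]:
        return {"W": self.dW, "b": self.db}


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, labels: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; returns (loss, dloss/dlogits)."""
    z = logits.astype(np.float64).ravel()
    y = labels.astype(np.float64).ravel()
    loss = np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = ((sigmoid(z) - y) / len(z)).astype(np.float32).reshape(logits.shape)
    return float(loss), grad


class Adam:
    def __init__(self, layers: List[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.layers = [l for l in layers if l.parameters()]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in l.parameters().items()}
            for l in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in l.parameters().items()}
            for l in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for i, layer in enumerate(self.layers):
            params, grads = layer.parameters(), layer.gradients()
            for k in params:
                self.m[i][k] = self.beta1 * self.m[i][k] + (1 - self.beta1) * grads[k]
                self.v[i][k] = self.beta2 * self.v[i][k] + (1 - self.beta2) * grads[k] ** 2
                mhat = self.m[i][k] / b1c
                vhat = self.v[i][k] / b2c
                update = mhat / (np.sqrt(vhat) + self.eps)
                if self.weight_decay and k == "W":  # decoupled, weights only
                    update = update + self.weight_decay * params[k]
                params[k] -= self.lr * update
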