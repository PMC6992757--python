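"""Minimal NumPy building blocks for the fully-convolutional localizer.

Convolutions are stride-1, zero-padded "same" cross-correlations with an
arbitrary dilation rate, computed by im2col + GEMM.  Gradients are
analytic: the input gradient of a same-padded stride-1 convolution is the
same-padded convolution of the output gradient with the spatially flipped,
channel-transposed kernel at the same dilation rate (exact, no numerical
approximation).  Tensors are ``(batch, rows, cols, channels)`` float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "Adam", "mae_loss"]


def _im2col(x: np.ndarray, kernel: int, dilation: int) -> np.ndarray:
    """Unfold ``(B,H,W,C)`` into ``(B*H*W, kernel*kernel*C)`` patch rows."""
    extent = (kernel - 1) * dilation + 1
    pad = extent // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    v = sliding_window_view(xp, (extent, extent), axis=(1, 2))
    v = v[..., ::dilation, ::dilation]            # (B,H,W,C,k,k) strided view
    v = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3))
    B, H, W = x.shape[:3]
    return v.reshape(B * H * W, kernel * kernel * x.shape[3])


class Conv2D:
    """Same-size convolution with fused activation.

    Parameters
    ----------
    kernel, c_in, c_out, dilation
        Square kernel size, channel counts, dilation rate (stride fixed 1).
    activation
        ``"relu"``, ``"tanh"`` or ``None`` (linear).
    rng
        Initialisation generator.  He scaling for rectifier layers, Xavier
        for the rest.
    """

    def __init__(self, kernel: int, c_in: int, c_out: int, dilation: int = 1,
                 activation: str | None = "relu",
                 rng: np.random.Generator | None = None) -> None:
        if kernel < 1 or c_in < 1 or c_out < 1 or dilation < 1:
            raise ValueError("kernel, channel counts and dilation must be >= 1")
        if activation not in ("relu", "tanh", None):
            raise ValueError(f"unknown activation: {activation!r}")
        rng = rng or np.random.default_rng()
        fan_in = kernel * kernel * c_in
        gain = np.sqrt(2.0 / fan_in) if activation == "relu" else np.sqrt(1.0 / fan_in)
        self.W = (gain * rng.standard_normal((kernel, kernel, c_in, c_out))
                  ).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel, self.c_in, self.c_out = kernel, c_in, c_out
        self.dilation, self.stride = dilation, 1
        self.activation = activation
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, H, W = x.shape[:3]
        if self.kernel == 1:
            cols = x.reshape(-1, self.c_in)
        else:
            cols = _im2col(x, self.kernel, self.dilation)
        y = cols @ self.W.reshape(-1, self.c_out) + self.b
        y = y.reshape(B, H, W, self.c_out)
        if self.activation == "relu":
            np.maximum(y, 0.0, out=y)
            act_cache = y > 0
        elif self.activation == "tanh":
            np.tanh(y, out=y)
            act_cache = y
        else:
            act_cache = None
        if train:
            self._cache = (cols, x.shape, act_cache)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a train-mode forward")
        cols, x_shape, act_cache = self._cache
        if self.activation == "relu":
            dy = dy * act_cache
        elif self.activation == "tanh":
            dy = dy * (1.0 - act_cache * act_cache)
        dym = dy.reshape(-1, self.c_out)
        self.dW = (cols.T @ dym).reshape(self.W.shape)
        self.db = dym.sum(axis=0)
        if self.kernel == 1:
            dx = (dym @ self.W.reshape(self.c_in, self.c_out).T).reshape(x_shape)
        else:
            w_t = self.W[::-1, ::-1].transpose(0, 1, 3, 2)  # (k,k,c_out,c_in)
            dcols = _im2col(dy.astype(np.float32, copy=False),
                            self.kernel, self.dilation)
            dx = (dcols @ w_t.reshape(-1, self.c_in)).reshape(x_shape)
        self._cache = None
        return dx

    def parameters(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class Adam:
    """Adaptive-moment gradient descent over a set of Conv2D layers."""

    def __init__(self, layers: list[Conv2D], learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p) for lay in layers for _, p, _ in lay.parameters()]
        self._v = [np.zeros_like(p) for lay in layers for _, p, _ in lay.parameters()]

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        i = 0
        for lay in self.layers:
            for _, p, g in lay.parameters():
                m, v = self._m[i], self._v[i]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
                i += 1


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its (sub)gradient w.r.t. ``pred``."""
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = np.sign(diff, dtype=np.float32) / diff.size
    return loss, grad
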