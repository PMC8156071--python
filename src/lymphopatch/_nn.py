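"""Minimal CNN layer kit: im2col convolutions, pooling, dense, Adam.

Everything is plain NumPy with explicit forward/backward passes, which
keeps training fully deterministic on one thread and makes exact input
gradients available for saliency. Shapes are channels-last, (N, H, W, C).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col3(x: np.ndarray) -> np.ndarray:
    """3x3 same-padding patch matrix: (N,H,W,C) -> (N*H*W, 9*C)."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,C,3,3)
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, 9 * c)
    return np.ascontiguousarray(cols)


class Conv3x3:
    """3x3 convolution, stride 1, same padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (9 * c_in))
        self.w = rng.normal(0.0, scale, size=(9 * c_in, c_out))
        self.b = np.zeros(c_out)
        self.c_in, self.c_out = c_in, c_out
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        cols = _im2col3(x)
        if train:
            self._cols, self._shape = cols, x.shape
        return (cols @ self.w + self.b).reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray):
        n, h, w, _ = self._shape
        dyf = dy.reshape(n * h * w, self.c_out)
        self.dw = self._cols.T @ dyf
        self.db = dyf.sum(axis=0)
        return self._input_grad(dy)

    def _input_grad(self, dy: np.ndarray) -> np.ndarray:
        # full correlation of dy with the spatially flipped, io-swapped kernel
        n, h, w, _ = dy.shape
        wk = self.w.reshape(3, 3, self.c_in, self.c_out)
        wk_flip = wk[::-1, ::-1].transpose(0, 1, 3, 2)  # (3,3,c_out,c_in)
        cols = _im2col3(dy)
        dx = cols @ wk_flip.reshape(9 * self.c_out, self.c_in)
        return dx.reshape(n, h, w, self.c_in)

    def input_grad_only(self, dy: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. input without touching weight gradients."""
        return self._input_grad(dy)

    def params_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def state(self):
        return [self.w, self.b]


class ReLU:
    n_params = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0)

    def forward_with_mask(self, x: np.ndarray):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; odd trailing rows/columns are cropped."""

    n_params = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : h2 * 2, : w2 * 2]
        xr = xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(n, h2, w2, c, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._in_shape = idx, x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self._scatter(dy, self._idx, self._in_shape)

    @staticmethod
    def _scatter(dy: np.ndarray, idx: np.ndarray, in_shape: tuple) -> np.ndarray:
        n, h, w, c = in_shape
        h2, w2 = h // 2, w // 2
        grid = np.zeros((n, h2, w2, c, 4), dtype=dy.dtype)
        np.put_along_axis(grid, idx[..., None], dy[..., None], axis=-1)
        grid = grid.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(in_shape, dtype=dy.dtype)
        dx[:, : h2 * 2, : w2 * 2] = grid.reshape(n, h2 * 2, w2 * 2, c)
        return dx


class GlobalAvgPool:
    n_params = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), self._in_shape).copy()


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    def input_grad_only(self, dy: np.ndarray) -> np.ndarray:
        return dy @ self.w.T

    def params_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def state(self):
        return [self.w, self.b]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y_onehot: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.sum(y_onehot * np.log(np.clip(p, 1e-12, None))) / n
    return loss, (p - y_onehot) / n


class Adam:
    """Adam with the standard default moment coefficients."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params_grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for i, (p, g) in enumerate(params_grads):
            m = self._m.setdefault(i, np.zeros_like(p))
            v = self._v.setdefault(i, np.zeros_like(p))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
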