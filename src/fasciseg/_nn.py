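"""Minimal numpy CNN engine used by the U-Net segmenter.

Implements exactly the layers a U-Net needs — 2D convolution (same padding),
ReLU, 2x2 max-pooling, 2x nearest-neighbor upsampling — with hand-written
backward passes, plus an Adam optimizer. Convolutions go through an im2col
patch matrix so both directions are single BLAS matmuls; the input gradient
is computed as a convolution of the output gradient with the spatially
flipped, in/out-transposed kernel, avoiding scatter-adds.

Arrays are NHWC. All ops preserve the floating dtype of their input, so the
same graph can be run in float32 (training) or float64 (numerical gradient
checks). Layers cache what their backward pass needs; call ``forward`` then
``backward`` in strict alternation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2", "Upsample2", "Adam"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, k*k*C) patch matrix with same padding.

    Filled by k*k shifted block copies of the padded input, which is much
    faster than transposing a sliding-window view.
    """
    n, h, w, c = x.shape
    if k == 1:
        return x.reshape(n * h * w, c)
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    cols = np.empty((n, h, w, k, k, c), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, :, i, j, :] = xp[:, i : i + h, j : j + w, :]
    return cols.reshape(n * h * w, k * k * c)


class Conv2D:
    """k x k convolution with same padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (k * k * c_in))
        self.kernel = rng.normal(0.0, std, size=(k, k, c_in, c_out)).astype(np.float32)
        self.bias = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.skip_input_grad = False  # set on the network's first layer
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None
        self.d_kernel = np.zeros_like(self.kernel)
        self.d_bias = np.zeros_like(self.bias)

    @property
    def params(self):
        return [self.kernel, self.bias]

    @property
    def grads(self):
        return [self.d_kernel, self.d_bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c_in = x.shape
        cols = _im2col(x, self.k)
        self._cols, self._xshape = cols, x.shape
        w2 = self.kernel.reshape(self.k * self.k * c_in, -1)
        y = cols @ w2 + self.bias
        return y.reshape(n, h, w, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        n, h, w, c_out = dy.shape
        dyf = dy.reshape(n * h * w, c_out)
        self.d_kernel[...] = (self._cols.T @ dyf).reshape(self.kernel.shape)
        self.d_bias[...] = dyf.sum(axis=0)
        self._cols = None
        if self.skip_input_grad:
            return None
        # dx = conv(dy, kernel flipped spatially, in/out channels swapped)
        kb = self.kernel[::-1, ::-1].transpose(0, 1, 3, 2)  # (k, k, c_out, c_in)
        cols_dy = _im2col(dy, self.k)
        dx = cols_dy @ np.ascontiguousarray(kb).reshape(self.k * self.k * c_out, -1)
        return dx.reshape(self._xshape)


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None
        self.params: list = []
        self.grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2. Ties share the gradient equally."""

    def __init__(self):
        self._mask = None
        self._inv_counts = None
        self.params: list = []
        self.grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {(h, w)}")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        mask = xr == y[:, :, None, :, None, :]
        self._mask = mask
        self._inv_counts = (1.0 / mask.sum(axis=(2, 4), keepdims=True)).astype(x.dtype)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, hh, ww, c = dy.shape
        g = self._mask * (dy[:, :, None, :, None, :] * self._inv_counts)
        return g.reshape(n, hh * 2, ww * 2, c)


class Upsample2:
    """2x nearest-neighbor upsampling."""

    def __init__(self):
        self.params: list = []
        self.grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Adam:
    """Adam over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
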