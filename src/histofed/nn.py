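"""Minimal NumPy neural-network layer kit with exact reverse-mode gradients.

Everything here is deterministic, float64 and single-threaded-reproducible:
a convolution, its adjoints, a transposed convolution defined as the exact
adjoint of the strided convolution, dense layers, pooling and pointwise
activations.  Same-padding follows the ``ceil(n / stride)`` output-size
convention, padding the extra pixel on the bottom/right, so stride-2 layers
halve even spatial sizes exactly.

Tensors are channels-last: images are ``(N, H, W, C)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def same_pad(n: int, k: int, s: int) -> tuple[int, int, int]:
    """(pad_before, pad_after, out_size) for same-padding, out = ceil(n/s)."""
    out = -(-n // s)
    total = max((out - 1) * s + k - n, 0)
    return total // 2, total - total // 2, out


def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Unfold same-padded x (N,H,W,C) into rows of k*k*C patch values."""
    n, h, w, c = x.shape
    pt, pb, oh = same_pad(h, k, stride)
    pl, pr, ow = same_pad(w, k, stride)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    # win: (N, OH, OW, C, k, k) -> rows ordered (k, k, C) to match weight layout
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
    return cols.reshape(n * oh * ow, k * k * c), (oh, ow)


def conv2d(x: np.ndarray, w: np.ndarray, stride: int):
    """Same-padded strided convolution.

    x: (N,H,W,Ci), w: (k,k,Ci,Co) -> y: (N,ceil(H/s),ceil(W/s),Co).
    Returns (y, cols) where cols is the im2col cache for the weight gradient.
    """
    k, _, ci, co = w.shape
    n = x.shape[0]
    cols, (oh, ow) = _im2col(x, k, stride)
    y = cols @ w.reshape(k * k * ci, co)
    return y.reshape(n, oh, ow, co), cols


def conv2d_input_grad(
    dy: np.ndarray, w: np.ndarray, in_hw: tuple[int, int], stride: int
) -> np.ndarray:
    """Adjoint of conv2d in its input: scatter dy back to (N, H, W, Ci)."""
    k, _, ci, co = w.shape
    n, oh, ow, _ = dy.shape
    h, wd = in_hw
    pt, pb, oh2 = same_pad(h, k, stride)
    pl, pr, ow2 = same_pad(wd, k, stride)
    if (oh2, ow2) != (oh, ow):
        raise ValueError(
            f"gradient spatial size {(oh, ow)} incompatible with input {in_hw} "
            f"at stride {stride}"
        )
    dcols = (dy.reshape(-1, co) @ w.reshape(-1, co).T).reshape(n, oh, ow, k, k, ci)
    dxp = np.zeros((n, h + pt + pb, wd + pl + pr, ci), dtype=dy.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + oh * stride : stride, j : j + ow * stride : stride] += (
                dcols[:, :, :, i, j, :]
            )
    return dxp[:, pt : pt + h, pl : pl + wd]


def conv2d_weight_grad(cols: np.ndarray, dy: np.ndarray, k: int, ci: int) -> np.ndarray:
    co = dy.shape[-1]
    return (cols.T @ dy.reshape(-1, co)).reshape(k, k, ci, co)


class Layer:
    """Base: parameterised, differentiable, stateless between forward calls."""

    name: str = ""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(self, name, ci, co, k, stride, rng, init_scale=2.0):
        self.name, self.ci, self.co, self.k, self.stride = name, ci, co, k, stride
        fan_in = k * k * ci
        self.w = rng.standard_normal((k, k, ci, co)) * np.sqrt(init_scale / fan_in)
        self.b = np.zeros(co)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._in_hw = None

    def params(self):
        return {f"{self.name}/w": self.w, f"{self.name}/b": self.b}

    def grads(self):
        return {f"{self.name}/w": self.dw, f"{self.name}/b": self.db}

    def forward(self, x):
        self._in_hw = x.shape[1:3]
        y, self._cols = conv2d(x, self.w, self.stride)
        return y + self.b

    def backward(self, dy):
        self.dw = conv2d_weight_grad(self._cols, dy, self.k, self.ci)
        self.db = dy.sum(axis=(0, 1, 2))
        return conv2d_input_grad(dy, self.w, self._in_hw, self.stride)


class ConvTranspose2D(Layer):
    """Transposed convolution: the exact adjoint of a same-padded strided conv.

    Maps (N, h, w, Ci) -> (N, out_h, out_w, Co) where (out_h, out_w) is given
    explicitly and must satisfy ceil(out/s) == in; this lets a decoder mirror
    an encoder trace exactly even for odd sizes.
    """

    def __init__(self, name, ci, co, k, stride, out_hw, rng, init_scale=2.0):
        self.name, self.ci, self.co, self.k, self.stride = name, ci, co, k, stride
        self.out_hw = tuple(out_hw)
        fan_in = k * k * ci
        # conv-orientation weight: the conv this layer is adjoint to maps Co -> Ci
        self.w = rng.standard_normal((k, k, co, ci)) * np.sqrt(init_scale / fan_in)
        self.b = np.zeros(co)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return {f"{self.name}/w": self.w, f"{self.name}/b": self.b}

    def grads(self):
        return {f"{self.name}/w": self.dw, f"{self.name}/b": self.db}

    def forward(self, x):
        for o, i in zip(self.out_hw, x.shape[1:3]):
            if -(-o // self.stride) != i:
                raise ValueError(
                    f"{self.name}: input size {x.shape[1:3]} cannot upsample to "
                    f"{self.out_hw} at stride {self.stride}"
                )
        self._x = x
        y = conv2d_input_grad(x, self.w, self.out_hw, self.stride)
        return y + self.b

    def backward(self, dy):
        dx, cols = conv2d(dy, self.w, self.stride)
        self.dw = conv2d_weight_grad(cols, self._x, self.k, self.co)
        self.db = dy.sum(axis=(0, 1, 2))
        return dx


class Dense(Layer):
    def __init__(self, name, ci, co, rng, init_scale=1.0):
        self.name = name
        self.w = rng.standard_normal((ci, co)) * np.sqrt(init_scale / ci)
        self.b = np.zeros(co)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return {f"{self.name}/w": self.w, f"{self.name}/b": self.b}

    def grads(self):
        return {f"{self.name}/w": self.dw, f"{self.name}/b": self.db}

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class GlobalAvgPool(Layer):
    """(N, H, W, C) -> (N, C), averaging over the spatial extent."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :], self._shape) / (h * w)


def mse(i: np.ndarray, o: np.ndarray) -> float:
    """Mean over all pixels/channels of the squared reconstruction error."""
    i = np.asarray(i, dtype=np.float64)
    o = np.asarray(o, dtype=np.float64)
    if i.shape != o.shape:
        raise ValueError(f"shape mismatch: input {i.shape} vs output {o.shape}")
    d = o - i
    return float(np.mean(d * d))


def mse_grad_wrt_output(i: np.ndarray, o: np.ndarray) -> np.ndarray:
    return 2.0 * (o - i) / o.size
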