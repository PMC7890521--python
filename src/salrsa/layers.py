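"""Network layer primitives: convolution, ReLU, max pooling, transposed convolution.

All layers operate on batched activation arrays of shape ``(N, H, W, C)``
(batch, height, width, channels).  Single-stimulus activations recorded for
analysis are exposed as ``(H, W, C)``; the width axis is *x*, the height
axis *y*, so element ``values[y, x, c]`` is the model neuron at spatial
location (x, y) in channel c.

The convolution is a cross-correlation (no kernel flip) with zero padding,
so spatial dimensions are preserved; pooling is the only downsampling stage
and the transposed convolution the only upsampling stage.  Every layer
implements ``forward`` and ``backward`` so the network can be trained with
plain reverse-mode gradients and no autodiff dependency.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2D",
    "TransposedConv2D",
    "correlate_same",
]


def _check_4d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 4:
        raise ValueError(f"expected (N, H, W, C) array, got shape {x.shape}")
    return x


def correlate_same(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Zero-padded 'same' cross-correlation of a batch with a filter bank.

    Parameters
    ----------
    x : (N, H, W, C_in)
    weights : (KH, KW, C_in, C_out), KH and KW odd.

    Returns
    -------
    (N, H, W, C_out) array where
    ``out[n, y, x, c] = sum_k sum_i sum_j w[i, j, k, c] * x[n, y+i-h, x+j-w, k]``
    with out-of-bounds input treated as zero.
    """
    x = _check_4d(x)
    kh, kw, c_in, _ = weights.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernel dims must be odd for symmetric zero padding")
    if x.shape[3] != c_in:
        raise ValueError(
            f"filter depth {c_in} does not match input channel count {x.shape[3]}"
        )
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    # windows: (N, H, W, C_in, KH, KW)
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))
    return np.einsum("nhwkij,ijko->nhwo", win, weights, optimize=True)


class Conv2D:
    """Stride-1 convolutional layer (cross-correlation) with zero padding.

    ``weights`` has shape (KH, KW, C_in, C_out); one scalar bias per filter
    (optional).  Output spatial dims equal input spatial dims.
    """

    kind = "conv"
    has_params = True

    def __init__(self, weights: np.ndarray, bias: np.ndarray | None = None):
        weights = np.asarray(weights, dtype=np.float64)
        if weights.ndim != 4:
            raise ValueError("conv weights must be (KH, KW, C_in, C_out)")
        self.weights = weights
        self.bias = None if bias is None else np.asarray(bias, dtype=np.float64)
        if self.bias is not None and self.bias.shape != (weights.shape[3],):
            raise ValueError("bias must be one scalar per filter")
        self.grad_weights = np.zeros_like(self.weights)
        self.grad_bias = None if self.bias is None else np.zeros_like(self.bias)
        self._win = None

    @property
    def out_channels(self) -> int:
        return self.weights.shape[3]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = _check_4d(x)
        kh, kw, c_in, _ = self.weights.shape
        if x.shape[3] != c_in:
            raise ValueError(
                f"filter depth {c_in} does not match input channels {x.shape[3]}"
            )
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        win = sliding_window_view(xp, (kh, kw), axis=(1, 2))
        if train:
            self._win = win
        out = np.einsum("nhwkij,ijko->nhwo", win, self.weights, optimize=True)
        if self.bias is not None:
            out += self.bias
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._win is None:
            raise RuntimeError("backward called before forward(train=True)")
        self.grad_weights = np.einsum(
            "nhwkij,nhwo->ijko", self._win, grad_out, optimize=True
        )
        if self.bias is not None:
            self.grad_bias = grad_out.sum(axis=(0, 1, 2))
        # gradient w.r.t. input: 'same' correlation with the spatially
        # flipped kernel, channels transposed
        w_flip = self.weights[::-1, ::-1].transpose(0, 1, 3, 2)
        return correlate_same(grad_out, w_flip)

    def params(self):
        if self.bias is not None:
            return [("weights", self.weights, self.grad_weights),
                    ("bias", self.bias, self.grad_bias)]
        return [("weights", self.weights, self.grad_weights)]


class ReLU:
    """Elementwise rectification max(0, v)."""

    kind = "relu"
    has_params = False

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class MaxPool2D:
    """Max pooling over (kernel x kernel) windows with the given stride.

    Channel count is unchanged; spatial dims shrink to
    ``(dim - kernel) // stride + 1``.
    """

    kind = "maxpool"
    has_params = False

    def __init__(self, kernel: int = 2, stride: int = 2):
        if stride < 1:
            raise ValueError("stride must be >= 1")
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        self.kernel = int(kernel)
        self.stride = int(stride)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = _check_4d(x)
        k, s = self.kernel, self.stride
        n, h, w, c = x.shape
        if k > h or k > w:
            raise ValueError(f"pooling kernel {k} larger than input {h}x{w}")
        win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::s, ::s]
        flat = win.reshape(win.shape[:4] + (k * k,))
        if train:
            argmax = flat.argmax(axis=-1)
            self._cache = (x.shape, argmax)
        return flat.max(axis=-1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        in_shape, argmax = self._cache
        k, s = self.kernel, self.stride
        n, ho, wo, c = grad_out.shape
        dx = np.zeros(in_shape)
        di, dj = argmax // k, argmax % k
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, None, None, :]
        rows = np.arange(ho)[None, :, None, None] * s + di
        cols = np.arange(wo)[None, None, :, None] * s + dj
        np.add.at(dx, (ni, rows, cols, ci), grad_out)
        return dx


class TransposedConv2D:
    """Transposed convolution: zero-stuffed upsampling followed by correlation.

    With stride ``s`` and kernel ``k`` (``k >= s``, ``k - s`` even) the
    output spatial dims are exactly ``s`` times the input dims:
    ``out[t] = sum_i x[i] * K[t - i*s + p]`` with crop ``p = (k - s) / 2``
    per side.  Used as the final upsampling stage producing the saliency
    map at canvas resolution.
    """

    kind = "deconv"
    has_params = True

    def __init__(self, weights: np.ndarray, stride: int,
                 bias: np.ndarray | None = None):
        weights = np.asarray(weights, dtype=np.float64)
        if weights.ndim != 4:
            raise ValueError("deconv weights must be (K, K, C_in, C_out)")
        k = weights.shape[0]
        if weights.shape[1] != k:
            raise ValueError("deconv kernel must be square")
        if k < stride or (k - stride) % 2 != 0:
            raise ValueError("need kernel >= stride with even kernel-stride gap")
        self.weights = weights
        self.stride = int(stride)
        self.bias = None if bias is None else np.asarray(bias, dtype=np.float64)
        self.grad_weights = np.zeros_like(self.weights)
        self.grad_bias = None if self.bias is None else np.zeros_like(self.bias)
        self._x = None

    @property
    def out_channels(self) -> int:
        return self.weights.shape[3]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = _check_4d(x)
        k = self.weights.shape[0]
        s = self.stride
        if x.shape[3] != self.weights.shape[2]:
            raise ValueError("deconv filter depth does not match input channels")
        n, h, w, _ = x.shape
        c_out = self.weights.shape[3]
        p = (k - s) // 2
        buf = np.zeros((n, (h - 1) * s + k, (w - 1) * s + k, c_out))
        for i in range(k):
            for j in range(k):
                val = np.einsum("nhwc,co->nhwo", x, self.weights[i, j],
                                optimize=True)
                buf[:, i:i + (h - 1) * s + 1:s, j:j + (w - 1) * s + 1:s] += val
        out = buf[:, p:p + h * s, p:p + w * s]
        if self.bias is not None:
            out = out + self.bias
        if train:
            self._x = x
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x = self._x
        k, s = self.weights.shape[0], self.stride
        n, h, w, c_in = x.shape
        p = (k - s) // 2
        # pad grad_out back to the uncropped buffer size
        gp = np.pad(grad_out, ((0, 0), (p, k - s - p), (p, k - s - p), (0, 0)))
        dx = np.zeros_like(x)
        for i in range(k):
            for j in range(k):
                sl = gp[:, i:i + (h - 1) * s + 1:s, j:j + (w - 1) * s + 1:s]
                dx += np.einsum("nhwo,co->nhwc", sl, self.weights[i, j],
                                optimize=True)
                self.grad_weights[i, j] = np.einsum(
                    "nhwc,nhwo->co", x, sl, optimize=True)
        if self.bias is not None:
            self.grad_bias = grad_out.sum(axis=(0, 1, 2))
        return dx

    def params(self):
        if self.bias is not None:
            return [("weights", self.weights, self.grad_weights),
                    ("bias", self.bias, self.grad_bias)]
        return [("weights", self.weights, self.grad_weights)]
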