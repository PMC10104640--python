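"""Minimal CNN building blocks in numpy with explicit backpropagation.

Layers keep their parameters in ``self.params`` / gradients in
``self.grads`` (parallel dicts of arrays) and cache forward activations for
the backward pass.  Everything operates on single-precision ``(N, C, H, W)``
tensors; randomness comes exclusively from the ``numpy.random.Generator``
passed at construction, so runs are reproducible bit-for-bit at a fixed
seed and thread count.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32  # single precision: ~2x faster matmuls, ample for training

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "ConvTranspose2x2",
    "Adam",
    "bce_loss",
    "collect_params",
]


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


def _conv_forward(x, w, pad):
    """Cross-correlation with 'same' padding; returns (out, padded windows)."""
    k = w.shape[-1]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    out = np.einsum("nchwij,ocij->nohw", win, w, optimize=True)
    return out, win


class Conv2d(Layer):
    """k x k convolution, stride 1, 'same' padding (k odd)."""

    def __init__(self, c_in, c_out, k, rng, bias=True):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * k * k))  # He initialization
        self.params["w"] = rng.normal(0.0, scale, size=(c_out, c_in, k, k)).astype(DTYPE)
        if bias:
            self.params["b"] = np.zeros(c_out, dtype=DTYPE)
        self.k, self.pad = k, k // 2

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        out, win = _conv_forward(x, self.params["w"], self.pad)
        if "b" in self.params:
            out = out + self.params["b"][None, :, None, None]
        self._win = win
        self._xshape = x.shape
        return out

    def backward(self, dout):
        w = self.params["w"]
        self.grads["w"] = np.einsum("nchwij,nohw->ocij", self._win, dout, optimize=True)
        if "b" in self.params:
            self.grads["b"] = dout.sum(axis=(0, 2, 3))
        # dx = correlation of dout with the flipped, transposed kernel
        w_flip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dx, _ = _conv_forward(dout, w_flip, self.pad)
        return dx


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.9, eps=1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=DTYPE)
        self.params["beta"] = np.zeros(c, dtype=DTYPE)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, dout):
        xhat, std = self._cache
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / std[None, :, None, None]
        return dx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2 (input H, W must be even)."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)  # ties -> first element, deterministic
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        mask = np.zeros(flat.shape, dtype=bool)
        np.put_along_axis(mask, idx[..., None], True, axis=-1)
        self._mask = mask
        self._shape = x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        dx = self._mask * dout[..., None]
        dx = dx.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(n, c, h, w)


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution, stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in, c_out, rng):
        super().__init__()
        scale = np.sqrt(2.0 / c_in)
        self.params["w"] = rng.normal(0.0, scale, size=(c_in, c_out, 2, 2)).astype(DTYPE)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        self._x = x
        n, c, h, w = x.shape
        out = np.einsum("ncij,coab->noiajb", x, self.params["w"], optimize=True)
        out = out.reshape(n, out.shape[1], h * 2, w * 2)
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout):
        n, o, h2, w2 = dout.shape
        d = dout.reshape(n, o, h2 // 2, 2, w2 // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        # d: n,o,i,j,a,b
        self.grads["w"] = np.einsum("ncij,noijab->coab", self._x, d, optimize=True)
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        dx = np.einsum("noijab,coab->ncij", d, self.params["w"], optimize=True)
        return dx


def bce_loss(pred, target, eps=1e-7):
    """Mean binary cross-entropy and its gradient wrt pred."""
    p = np.clip(pred, eps, 1.0 - eps)
    loss = float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))
    grad = (p - target) / (p * (1.0 - p)) / p.size
    return loss, grad


def collect_params(layers):
    """Flatten (layer, name) -> array pairs for the optimizer."""
    out = []
    for layer in layers:
        for name in layer.params:
            out.append((layer, name))
    return out


class Adam:
    def __init__(self, param_refs, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.refs = param_refs
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(layer.params[name]) for layer, name in param_refs]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in param_refs]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (layer, name) in enumerate(self.refs):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for layer, name in self.refs:
            layer.grads.pop(name, None)
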