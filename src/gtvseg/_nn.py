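"""Minimal CPU neural-network layers with explicit backpropagation.

Everything operates on float32 arrays in ``(N, C, X, Y, Z)`` layout. Each
layer caches what its backward pass needs during ``forward`` and returns
input gradients from ``backward``; trainable arrays are :class:`Param`
objects collected by the model and updated by :class:`Adam`.

Convolutions are stride-1, zero-padded to "same" size, computed as one
BLAS contraction per kernel offset (k³ matmuls over shifted views), which
keeps the memory pattern sequential and is fast enough for the patch
sizes this package trains at; the backward pass mirrors the same loop.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = [
    "Param",
    "Conv3d",
    "InstanceNorm3d",
    "ReLU",
    "ConvBlock",
    "MaxPool2x",
    "NearestUpsample2x",
    "Adam",
    "softmax",
    "dice_loss_and_grad",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray, dtype=np.float32):
        self.value = np.ascontiguousarray(value, dtype=dtype)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv3d:
    """3D convolution, stride 1, same padding, odd kernel, with bias."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, dtype=np.float32):
        if k < 1 or k % 2 == 0:
            raise ValueError(f"kernel edge must be odd and >= 1, got {k}")
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k**3
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k, k)), dtype)
        self.b = Param(np.zeros(cout), dtype)
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, cin, X, Y, Z = x.shape
        assert cin == self.cin, (cin, self.cin)
        k, pad = self.k, self.k // 2
        if pad:
            xp = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
        else:
            xp = x
        # accumulate one BLAS contraction per kernel offset in
        # (cout, n, X, Y, Z) layout, transposing once at the end
        acc = np.zeros((self.cout, n, X, Y, Z), dtype=x.dtype)
        for i, j, l in product(range(k), range(k), range(k)):
            xs = xp[:, :, i : i + X, j : j + Y, l : l + Z]
            acc += np.tensordot(self.w.value[:, :, i, j, l], xs, axes=(1, 1))
        out = acc.transpose(1, 0, 2, 3, 4) + self.b.value.reshape(1, -1, 1, 1, 1)
        if train:
            self._cache = (xp, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, xshape = self._cache
        n, cin, X, Y, Z = xshape
        k, pad = self.k, self.k // 2
        self.b.grad += dout.sum(axis=(0, 2, 3, 4))
        dxp = np.zeros_like(xp)
        for i, j, l in product(range(k), range(k), range(k)):
            xs = xp[:, :, i : i + X, j : j + Y, l : l + Z]
            self.w.grad[:, :, i, j, l] += np.tensordot(
                dout, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4])
            )
            dxp[:, :, i : i + X, j : j + Y, l : l + Z] += np.tensordot(
                dout, self.w.value[:, :, i, j, l], axes=(1, 0)
            ).transpose(0, 4, 1, 2, 3)
        if pad == 0:
            return dxp
        return dxp[:, :, pad : pad + X, pad : pad + Y, pad : pad + Z]


class InstanceNorm3d:
    """Per-sample, per-channel normalization with learnable affine."""

    def __init__(self, c: int, eps: float = 1e-5, dtype=np.float32):
        self.eps = eps
        self.gamma = Param(np.ones(c), dtype)
        self.beta = Param(np.zeros(c), dtype)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        sp = (2, 3, 4)
        mu = x.mean(axis=sp, keepdims=True)
        var = x.var(axis=sp, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._cache = (xhat, inv)
        g = self.gamma.value.reshape(1, -1, 1, 1, 1)
        b = self.beta.value.reshape(1, -1, 1, 1, 1)
        return (g * xhat + b).astype(x.dtype)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        sp = (2, 3, 4)
        m = xhat[0, 0].size
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3, 4))
        self.beta.grad += dout.sum(axis=(0, 2, 3, 4))
        dxhat = dout * self.gamma.value.reshape(1, -1, 1, 1, 1)
        dx = (
            inv
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=sp, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=sp, keepdims=True)
            )
        )
        return dx.astype(dout.dtype)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class ConvBlock:
    """Conv → instance norm → ReLU (the network's repeating unit)."""

    def __init__(self, cin, cout, k, rng, norm: bool = True, dtype=np.float32):
        self.layers = [Conv3d(cin, cout, k, rng, dtype)]
        if norm:
            self.layers.append(InstanceNorm3d(cout, dtype=dtype))
        self.layers.append(ReLU())

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class MaxPool2x:
    """2×2×2 max pooling; spatial dims must be even."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, X, Y, Z = x.shape
        if X % 2 or Y % 2 or Z % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {(X, Y, Z)}")
        xr = (
            x.reshape(n, c, X // 2, 2, Y // 2, 2, Z // 2, 2)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(n, c, X // 2, Y // 2, Z // 2, 8)
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, xshape = self._cache
        n, c, X, Y, Z = xshape
        dxr = np.zeros((n, c, X // 2, Y // 2, Z // 2, 8), dtype=dout.dtype)
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        return (
            dxr.reshape(n, c, X // 2, Y // 2, Z // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(xshape)
        )


class NearestUpsample2x:
    """Nearest-neighbor doubling of every spatial dimension."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, X2, Y2, Z2 = dout.shape
        return dout.reshape(n, c, X2 // 2, 2, Y2 // 2, 2, Z2 // 2, 2).sum(axis=(3, 5, 7))


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self, lr: float | None = None) -> None:
        if lr is not None:
            self.lr = lr
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def dice_loss_and_grad(logits: np.ndarray, onehot: np.ndarray, eps: float = 1e-7):
    """Present-class batch Dice loss and its gradient w.r.t. the logits.

    ``logits`` and one-hot ``onehot`` have shape ``(N, C, X, Y, Z)``. The
    loss matches :func:`gtvseg.losses_metrics.dice_loss` on
    ``softmax(logits)``; the gradient folds the softmax Jacobian in
    analytically.
    """
    probs = softmax(logits.astype(np.float64), axis=1)
    onehot = onehot.astype(np.float64)
    axes = (0, 2, 3, 4)
    y_sum = onehot.sum(axis=axes)
    present = y_sum > 0
    if not present.any():
        raise ValueError("ground truth contains no class at all")
    n_present = int(present.sum())
    dl_dp = np.zeros_like(probs)
    terms = []
    for c in np.flatnonzero(present):
        inter = (onehot[:, c] * probs[:, c]).sum()
        denom = y_sum[c] + probs[:, c].sum() + eps
        terms.append(1.0 - 2.0 * inter / denom)
        dl_dp[:, c] = (-2.0 * onehot[:, c] / denom + 2.0 * inter / denom**2) / n_present
    dot = (dl_dp * probs).sum(axis=1, keepdims=True)
    dlogits = probs * (dl_dp - dot)
    return float(np.mean(terms)), dlogits.astype(logits.dtype)
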