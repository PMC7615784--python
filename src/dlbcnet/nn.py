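"""Compact feed-forward neural-network toolkit.

Layers carry their own parameters and gradients and implement explicit
forward/backward passes on numpy arrays (images in NCHW layout).  This is
deliberately small: it supports exactly the architectures used elsewhere in
the package — a dense/conv trunk with batch normalization, the six-layer
classifier head, and the generator/discriminator pair — trained with Adam.

Conventions
-----------
* ``forward(x, train=...)`` caches whatever ``backward`` needs.
* ``backward(dout)`` accumulates parameter gradients in ``layer.grads`` and
  returns the gradient with respect to the layer input.
* Stochastic layers (dropout) draw from a ``numpy.random.Generator`` supplied
  via :meth:`Sequential.set_rng`, so a whole network is reproducible from one
  seed.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class; parameterless layers inherit the empty dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._s = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self._s

    def backward(self, dout):
        return dout * self._s * (1.0 - self._s)


class Tanh(Layer):
    def forward(self, x, train=False):
        self._t = np.tanh(x)
        return self._t

    def backward(self, dout):
        return dout * (1.0 - self._t**2)


class Softmax(Layer):
    """Row-wise softmax with the full Jacobian in the backward pass."""

    def forward(self, x, train=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=-1, keepdims=True)
        return self._p

    def backward(self, dout):
        p = self._p
        return p * (dout - (dout * p).sum(axis=-1, keepdims=True))


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("dropout layer used in train mode without an rng")
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class BatchNorm(Layer):
    """Batch normalization over (N,) features or (N,C,H,W) channels.

    Trainable scale/shift only; running statistics are buffers updated with
    exponential momentum in train mode and used verbatim at inference.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(n_features), "beta": np.zeros(n_features)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def _axes_and_shape(self, x):
        if x.ndim == 2:
            return (0,), (1, -1)
        if x.ndim == 4:
            return (0, 2, 3), (1, -1, 1, 1)
        raise ValueError(f"BatchNorm expects 2-D or 4-D input, got {x.ndim}-D")

    def forward(self, x, train=False):
        axes, shape = self._axes_and_shape(x)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu.reshape(shape)) * self._invstd.reshape(shape)
        self._axes, self._shape = axes, shape
        self._n = x.size // x.shape[1] if x.ndim == 4 else x.shape[0]
        self._train = train
        return self.params["gamma"].reshape(shape) * self._xhat + self.params["beta"].reshape(shape)

    def backward(self, dout):
        axes, shape = self._axes, self._shape
        xhat = self._xhat
        self.grads["gamma"] += (dout * xhat).sum(axis=axes)
        self.grads["beta"] += dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"].reshape(shape)
        if not self._train:
            return dxhat * self._invstd.reshape(shape)
        n = self._n
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        return (self._invstd.reshape(shape) / n) * (n * dxhat - s1 - xhat * s2)


def _im2col(x, kh, kw, stride, pad):
    n, c, h, w = x.shape
    hp = (h + 2 * pad - kh) // stride + 1
    wp = (w + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, kh, kw, hp, wp), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + stride * hp : stride, j : j + stride * wp : stride]
    return cols.reshape(n, c * kh * kw, hp * wp), (hp, wp)


def _col2im(dcols, xshape, kh, kw, stride, pad, hp, wp):
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, kh, kw, hp, wp)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * hp : stride, j : j + stride * wp : stride] += dcols[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv2d(Layer):
    """Same-style 2-D convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None):
        super().__init__()
        self.k, self.stride = kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.params = {
            "W": rng.normal(0.0, scale, size=(c_out, c_in * kernel * kernel)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False):
        self._xshape = x.shape
        self._cols, (hp, wp) = _im2col(x, self.k, self.k, self.stride, self.pad)
        self._hw = (hp, wp)
        out = np.einsum("ok,nkl->nol", self.params["W"], self._cols)
        out += self.params["b"][None, :, None]
        return out.reshape(x.shape[0], -1, hp, wp)

    def backward(self, dout):
        n, co, hp, wp = dout.shape
        dflat = dout.reshape(n, co, hp * wp)
        self.grads["W"] += np.einsum("nol,nkl->ok", dflat, self._cols)
        self.grads["b"] += dflat.sum(axis=(0, 2))
        dcols = np.einsum("ok,nol->nkl", self.params["W"], dflat)
        return _col2im(dcols, self._xshape, self.k, self.k, self.stride, self.pad, hp, wp)


class MaxPool2d(Layer):
    """2x2 max pooling on even spatial dims; gradient routed to the max."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2d requires even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        # if a 2x2 window ties, split gradient equally between the maxima
        self._mask = self._mask / self._mask.sum(axis=(3, 5), keepdims=True)
        self._shape = x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        d = dout[:, :, :, None, :, None] * self._mask
        return d.reshape(n, c, h, w)


class UpsampleNearest(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        super().__init__()
        self.shape = shape

    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Sequential:
    """An ordered chain of layers with a shared dropout rng."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def set_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grads(self):
        for layer in self.layers:
            layer.zero_grads()

    def parameters(self):
        """Yield (layer, name, array) triples for every trainable parameter."""
        for layer in self.layers:
            for name, arr in layer.params.items():
                yield layer, name, arr

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All parameters and buffers, keyed by position, for serialization."""
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"{i}.{name}"] = arr
            if isinstance(layer, BatchNorm):
                out[f"{i}.running_mean"] = layer.running_mean
                out[f"{i}.running_var"] = layer.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name][...] = state[f"{i}.{name}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"{i}.running_mean"]
                layer.running_var[...] = state[f"{i}.running_var"]


class Adam:
    """Adam over an explicit parameter list; updates arrays in place."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.triples = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for _, _, p in self.triples]
        self.v = [np.zeros_like(p) for _, _, p in self.triples]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (layer, name, p) in enumerate(self.triples):
            g = layer.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
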