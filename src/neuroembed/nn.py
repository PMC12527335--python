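"""Minimal 3D convolutional network engine in numpy.

No deep-learning framework ships with the target environment, so the
handful of layer types the autoencoders need are implemented here with
explicit forward/backward passes: Conv3d (k=3, s=1, p=1), transposed
Conv3d (k=2, s=2), batch norm, ReLU, 2x2x2 max pooling, dropout and a
dense layer, plus Adam.  Tensors are (N, C, D, H, W) numpy arrays.

The implementation favours clarity and BLAS-friendly reshapes (im2col
via ``sliding_window_view``) over generality: strides, dilation and
other kernel sizes are not supported because the architectures here
never use them.  Every layer's gradients are verified against numerical
differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    """Base class: parameters and their gradients live in two dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grad(self):
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


def _he_init(rng, shape, fan_in, dtype=DTYPE):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


def _conv3d_raw(x, w):
    """Valid correlation of padded x (N,C,D,H,W) with w (O,C,3,3,3)."""
    n = x.shape[0]
    win = sliding_window_view(x, (3, 3, 3), axis=(2, 3, 4))
    # win: (N, C, D, H, W, 3, 3, 3) -> (N*DHW, C*27)
    d, h, wd = win.shape[2:5]
    patches = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * d * h * wd, -1)
    out = patches @ w.reshape(w.shape[0], -1).T
    return out.reshape(n, d, h, wd, w.shape[0]).transpose(0, 4, 1, 2, 3), patches


class Conv3d(Layer):
    """3D convolution, kernel 3, stride 1, padding 1 (shape-preserving)."""

    def __init__(self, c_in, c_out, rng):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params["w"] = _he_init(rng, (c_out, c_in, 3, 3, 3), c_in * 27)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)
        self.zero_grad()

    def forward(self, x):
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        out, patches = _conv3d_raw(xp, self.params["w"])
        self._patches = patches
        self._n_spatial = x.shape[2:]
        return out + self.params["b"][None, :, None, None, None]

    def backward(self, dout):
        n, o = dout.shape[0], dout.shape[1]
        dmat = dout.transpose(0, 2, 3, 4, 1).reshape(-1, o)
        self.grads["w"] += (self._patches.T @ dmat).T.reshape(self.params["w"].shape)
        self.grads["b"] += dmat.sum(axis=0)
        # dx = correlation of padded dout with spatially flipped, transposed w
        wt = self.params["w"][:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        dp = np.pad(dout, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        dx, _ = _conv3d_raw(dp, np.ascontiguousarray(wt))
        self._patches = None
        return dx


class ConvTranspose3d(Layer):
    """Transposed 3D convolution, kernel 2, stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in, c_out, rng):
        super().__init__()
        self.params["w"] = _he_init(rng, (c_in, c_out, 2, 2, 2), c_in * 8)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)
        self.zero_grad()

    def forward(self, x):
        self._x = x
        n, c, d, h, w = x.shape
        o = self.params["w"].shape[1]
        y = np.einsum("ncdhw,coijk->nodihjwk", x, self.params["w"], optimize=True)
        y = y.reshape(n, o, 2 * d, 2 * h, 2 * w)
        return y + self.params["b"][None, :, None, None, None]

    def backward(self, dout):
        n, o, dd, hh, ww = dout.shape
        d6 = dout.reshape(n, o, dd // 2, 2, hh // 2, 2, ww // 2, 2)
        self.grads["w"] += np.einsum("ncdhw,nodihjwk->coijk", self._x, d6,
                                     optimize=True).astype(DTYPE, copy=False)
        self.grads["b"] += dout.sum(axis=(0, 2, 3, 4))
        dx = np.einsum("nodihjwk,coijk->ncdhw", d6, self.params["w"], optimize=True)
        self._x = None
        return dx.astype(dout.dtype, copy=False)


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=DTYPE)
        self.params["beta"] = np.zeros(c, dtype=DTYPE)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.momentum, self.eps = momentum, eps
        self.zero_grad()

    def _bc(self, v):
        return v[None, :, None, None, None]

    def forward(self, x):
        axes = (0, 2, 3, 4)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - self._bc(mean)) * self._bc(self._inv_std)
        return self._bc(self.params["gamma"]) * self._xhat + self._bc(self.params["beta"])

    def backward(self, dout):
        axes = (0, 2, 3, 4)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        self.grads["gamma"] += (dout * self._xhat).sum(axis=axes)
        self.grads["beta"] += dout.sum(axis=axes)
        dxhat = dout * self._bc(self.params["gamma"])
        if not self.training:
            return dxhat * self._bc(self._inv_std)
        t1 = m * dxhat
        t2 = dxhat.sum(axis=axes)
        t3 = self._xhat * (dxhat * self._xhat).sum(axis=axes)[None, :, None, None, None]
        dx = (self._bc(self._inv_std) / m) * (t1 - self._bc(t2) - t3)
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool3d(Layer):
    """2x2x2 max pooling; odd trailing slices are dropped (floor halving)."""

    def forward(self, x):
        n, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, :, : 2 * d2, : 2 * h2, : 2 * w2]
        xb = xc.reshape(n, c, d2, 2, h2, 2, w2, 2)
        xb = xb.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d2, h2, w2, 8)
        self._arg = xb.argmax(axis=-1)
        return np.take_along_axis(xb, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, d2, h2, w2 = dout.shape
        db = np.zeros((n, c, d2, h2, w2, 8), dtype=dout.dtype)
        np.put_along_axis(db, self._arg[..., None], dout[..., None], axis=-1)
        db = db.reshape(n, c, d2, h2, w2, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :, : 2 * d2, : 2 * h2, : 2 * w2] = db.reshape(
            n, c, 2 * d2, 2 * h2, 2 * w2)
        return dx


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate, rng):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x):
        if not self.training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Linear(Layer):
    def __init__(self, d_in, d_out, rng):
        super().__init__()
        self.params["w"] = _he_init(rng, (d_in, d_out), d_in)
        self.params["b"] = np.zeros(d_out, dtype=DTYPE)
        self.zero_grad()

    def forward(self, x):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        self.grads["w"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        dx = dout @ self.params["w"].T
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def iter_layers(layer):
    """Depth-first iteration over leaf layers."""
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from iter_layers(sub)
    else:
        yield layer


def set_training(root_layers, flag: bool):
    for layer in root_layers:
        for leaf in iter_layers(layer):
            leaf.training = flag


def named_parameters(root_layers):
    """(path, layer, name) triples for every parameter array."""
    out = []
    for i, layer in enumerate(root_layers):
        for j, leaf in enumerate(iter_layers(layer)):
            for name in leaf.params:
                out.append((f"{i}.{j}.{name}", leaf, name))
    return out


def zero_grads(root_layers):
    for layer in root_layers:
        for leaf in iter_layers(layer):
            leaf.zero_grad()


class Adam:
    """Adam optimizer over a list of (path, layer, name) parameter refs."""

    def __init__(self, param_refs, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.refs = param_refs
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = {p: np.zeros_like(layer.params[n]) for p, layer, n in param_refs}
        self.v = {p: np.zeros_like(layer.params[n]) for p, layer, n in param_refs}

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for path, layer, name in self.refs:
            g = layer.grads[name]
            self.m[path] = self.b1 * self.m[path] + (1 - self.b1) * g
            self.v[path] = self.b2 * self.v[path] + (1 - self.b2) * g * g
            mhat = self.m[path] / b1t
            vhat = self.v[path] / b2t
            layer.params[name] -= (self.lr * mhat /
                                   (np.sqrt(vhat) + self.eps)).astype(
                                       layer.params[name].dtype, copy=False)
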