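"""Minimal define-by-run neural-network layers with hand-derived backprop.

Each layer caches what its backward pass needs during ``forward`` and
returns the input gradient from ``backward`` while accumulating parameter
gradients in place.  Layers are single-use per step (one forward, then one
backward), which is all the training loop and saliency computation require.
"""

from __future__ import annotations

import numpy as np

from .functional import im2col, col2im

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "Dropout",
]


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Module:
    """Base class: parameter discovery, train/eval mode, dtype casting."""

    def __init__(self):
        self.training = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    def _children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Parameter]:
        params = [v for v in self.__dict__.values() if isinstance(v, Parameter)]
        for child in self._children():
            params.extend(child.parameters())
        return params

    def train(self):
        self.training = True
        for c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for c in self._children():
            c.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def astype(self, dtype):
        for p in self.parameters():
            p.value = p.value.astype(dtype)
            p.grad = p.grad.astype(dtype)
        for c in [self] + list(self._walk()):
            for name, val in list(c.__dict__.items()):
                if isinstance(val, np.ndarray) and val.dtype.kind == "f":
                    setattr(c, name, val.astype(dtype))
        return self

    def _walk(self):
        for c in self._children():
            yield c
            yield from c._walk()

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dy, need_input_grad: bool = True):
        for layer in reversed(self.layers[1:]):
            dy = layer.backward(dy)
        first = self.layers[0]
        if not need_input_grad and isinstance(first, Conv2d):
            return first.backward(dy, need_dx=False)
        return first.backward(dy)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x):
        k, s, p = self.kernel, self.stride, self.pad
        cols = im2col(x, k, k, s, p)  # (B, OH, OW, C, k, k)
        b, oh, ow = cols.shape[:3]
        cols2 = cols.reshape(b * oh * ow, -1)
        w2 = self.weight.value.reshape(self.out_ch, -1)
        y = cols2 @ w2.T
        if self.bias is not None:
            y += self.bias.value
        self._cache = (x.shape, cols2, (b, oh, ow))
        return y.reshape(b, oh, ow, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy, need_dx: bool = True):
        x_shape, cols2, (b, oh, ow) = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        dy2 = dy.transpose(0, 2, 3, 1).reshape(b * oh * ow, self.out_ch)
        self.weight.grad += (dy2.T @ cols2).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dy2.sum(axis=0)
        self._cache = None
        if not need_dx:
            return None
        dcols2 = dy2 @ self.weight.value.reshape(self.out_ch, -1)
        dcols = dcols2.reshape(b, oh, ow, self.in_ch, k, k)
        return col2im(dcols, x_shape, k, k, s, p)


class BatchNorm2d(Module):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.n_ch, self.momentum, self.eps = n_ch, momentum, eps
        self.gamma = Parameter(np.ones(n_ch, dtype=np.float32))
        self.beta = Parameter(np.zeros(n_ch, dtype=np.float32))
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)

    def forward(self, x):
        if self.training:
            n = x.shape[0] * x.shape[2] * x.shape[3]
            mean = np.einsum("bchw->c", x) / n
            var = np.einsum("bchw,bchw->c", x, x) / n - mean * mean
            np.maximum(var, 0.0, out=var)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                self.running_mean.dtype
            )
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, dy):
        xhat, inv_std = self._cache
        dg = np.einsum("bchw,bchw->c", dy, xhat)
        db = np.einsum("bchw->c", dy)
        self.gamma.grad += dg
        self.beta.grad += db
        g = self.gamma.value[:, None, None]
        if not self.training:
            self._cache = None
            return dy * (g * inv_std[:, None, None])
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        # dL/dx for batch statistics: (dxhat - mean(dxhat) - xhat*mean(dxhat*xhat)) * inv_std
        dx = dy - (db / n)[:, None, None] - xhat * (dg / n)[:, None, None]
        dx *= (g * inv_std[:, None, None])
        self._cache = None
        return dx


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, pad: int = 0):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x):
        k, s, p = self.kernel, self.stride, self.pad
        xp = x
        if p > 0:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        cols = im2col(xp, k, k, s, 0)  # (B, OH, OW, C, k, k)
        b, oh, ow, c = cols.shape[:4]
        flat = cols.reshape(b, oh, ow, c, k * k)
        idx = flat.argmax(axis=-1)
        self._cache = (x.shape, xp.shape, idx)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0].transpose(
            0, 3, 1, 2
        )

    def backward(self, dy):
        x_shape, xp_shape, idx = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        b, oh, ow, c = idx.shape[0], idx.shape[1], idx.shape[2], idx.shape[3]
        dcols = np.zeros((b, oh, ow, c, k * k), dtype=dy.dtype)
        np.put_along_axis(
            dcols, idx[..., None], dy.transpose(0, 2, 3, 1)[..., None], axis=-1
        )
        dxp = col2im(dcols.reshape(b, oh, ow, c, k, k), xp_shape, k, k, s, 0)
        self._cache = None
        if p > 0:
            return dxp[:, :, p : p + x_shape[2], p : p + x_shape[3]]
        return dxp


class GlobalAvgPool(Module):
    """(B, C, H, W) -> (B, C) spatial mean."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        b, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))

    def forward(self, x):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy):
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        dx = dy @ self.weight.value
        self._x = None
        return dx


class Dropout(Module):
    """Inverted dropout; the mask RNG is owned by the layer for determinism."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x):
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask
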