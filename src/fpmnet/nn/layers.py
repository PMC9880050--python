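"""Minimal CNN layer zoo with explicit forward/backward passes.

All feature maps are ``(N, C, H, W)`` numpy arrays.  Each layer caches what
its backward pass needs during ``forward`` and releases it after ``backward``;
a layer instance therefore appears exactly once in a network graph.

Convolutions are im2col/col2im based so the heavy lifting is a single BLAS
matmul per layer.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: child/parameter registration and train/eval switching."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def add_param(self, name: str, value: np.ndarray) -> Parameter:
        p = Parameter(value)
        self._params[name] = p
        return p

    def add_child(self, name: str, child: "Module") -> "Module":
        self._children[name] = child
        return child

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name if not prefix else f"{prefix}.{name}"), p
        for cname, child in self._children.items():
            sub = cname if not prefix else f"{prefix}.{cname}"
            yield from child.named_parameters(sub)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for child in self._children.values():
            child.set_training(mode)

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


def he_uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _same_padding(size: int, k: int, stride: int, dilation: int) -> tuple[int, int]:
    """Asymmetric SAME padding (before, after) for one spatial axis."""
    eff = dilation * (k - 1) + 1
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + eff - size, 0)
    return total // 2, total - total // 2


def im2col(x, kh, kw, stride, dilation, pads):
    """(N,C,H,W) -> (N, C*kh*kw, L) patch matrix; also returns (oh, ow)."""
    n, c, h, w = x.shape
    (pt, pb), (pl, pr) = pads
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    hp, wp = h + pt + pb, w + pl + pr
    oh = (hp - dilation * (kh - 1) - 1) // stride + 1
    ow = (wp - dilation * (kw - 1) - 1) // stride + 1
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            ii, jj = i * dilation, j * dilation
            cols[:, :, i, j] = xp[:, :, ii:ii + stride * oh:stride,
                                  jj:jj + stride * ow:stride]
    return cols.reshape(n, c * kh * kw, oh * ow), (oh, ow)


def col2im(cols, x_shape, kh, kw, stride, dilation, pads, out_hw):
    """Adjoint of :func:`im2col`: scatter-add patches back onto the image."""
    n, c, h, w = x_shape
    (pt, pb), (pl, pr) = pads
    oh, ow = out_hw
    xp = np.zeros((n, c, h + pt + pb, w + pl + pr), dtype=cols.dtype)
    cols6 = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            ii, jj = i * dilation, j * dilation
            xp[:, :, ii:ii + stride * oh:stride,
               jj:jj + stride * ow:stride] += cols6[:, :, i, j]
    return xp[:, :, pt:pt + h, pl:pl + w]


class Conv2d(Module):
    """Standard 2-D convolution, SAME padding, optional stride/dilation."""

    def __init__(self, c_in, c_out, kernel_size, rng, stride=1, dilation=1,
                 bias=True, dtype=np.float32):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.k = kernel_size
        self.stride, self.dilation = stride, dilation
        fan_in = c_in * kernel_size * kernel_size
        self.weight = self.add_param(
            "weight", he_uniform(rng, (c_out, c_in, self.k, self.k), fan_in, dtype))
        self.bias = self.add_param("bias", np.zeros(c_out, dtype=dtype)) if bias else None
        self._cache = None

    def forward(self, x):
        pads = (_same_padding(x.shape[2], self.k, self.stride, self.dilation),
                _same_padding(x.shape[3], self.k, self.stride, self.dilation))
        cols, (oh, ow) = im2col(x, self.k, self.k, self.stride, self.dilation, pads)
        w2 = self.weight.value.reshape(self.c_out, -1)
        y = np.matmul(w2, cols)
        if self.bias is not None:
            y += self.bias.value[None, :, None]
        self._cache = (x.shape, cols, pads, (oh, ow))
        return y.reshape(x.shape[0], self.c_out, oh, ow)

    def backward(self, grad):
        x_shape, cols, pads, out_hw = self._cache
        self._cache = None
        n = grad.shape[0]
        g = grad.reshape(n, self.c_out, -1)
        w2 = self.weight.value.reshape(self.c_out, -1)
        self.weight.grad += np.einsum("nol,nkl->ok", g, cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 2))
        dcols = np.matmul(w2.T, g)
        return col2im(dcols, x_shape, self.k, self.k, self.stride,
                      self.dilation, pads, out_hw)


class DepthwiseConv2d(Module):
    """Per-channel spatial convolution (the depthwise half of a separable conv)."""

    def __init__(self, channels, kernel_size, rng, stride=1, dilation=1,
                 bias=True, dtype=np.float32):
        super().__init__()
        self.c = channels
        self.k = kernel_size
        self.stride, self.dilation = stride, dilation
        fan_in = kernel_size * kernel_size
        self.weight = self.add_param(
            "weight", he_uniform(rng, (channels, self.k, self.k), fan_in, dtype))
        self.bias = self.add_param("bias", np.zeros(channels, dtype=dtype)) if bias else None
        self._cache = None

    def forward(self, x):
        pads = (_same_padding(x.shape[2], self.k, self.stride, self.dilation),
                _same_padding(x.shape[3], self.k, self.stride, self.dilation))
        cols, (oh, ow) = im2col(x, self.k, self.k, self.stride, self.dilation, pads)
        n = x.shape[0]
        cols4 = cols.reshape(n, self.c, self.k * self.k, -1)
        w2 = self.weight.value.reshape(self.c, -1)
        y = np.einsum("nckl,ck->ncl", cols4, w2)
        if self.bias is not None:
            y += self.bias.value[None, :, None]
        self._cache = (x.shape, cols4, pads, (oh, ow))
        return y.reshape(n, self.c, oh, ow)

    def backward(self, grad):
        x_shape, cols4, pads, out_hw = self._cache
        self._cache = None
        n = grad.shape[0]
        g = grad.reshape(n, self.c, -1)
        self.weight.grad += np.einsum("ncl,nckl->ck", g, cols4).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 2))
        w2 = self.weight.value.reshape(self.c, -1)
        dcols = np.einsum("ncl,ck->nckl", g, w2).reshape(n, self.c * self.k * self.k, -1)
        return col2im(dcols, x_shape, self.k, self.k, self.stride,
                      self.dilation, pads, out_hw)


class ConvTranspose2d(Module):
    """Stride-s transposed convolution (k == stride, so output is exactly s*H)."""

    def __init__(self, c_in, c_out, rng, kernel_size=2, stride=2, bias=True,
                 dtype=np.float32):
        super().__init__()
        if kernel_size != stride:
            raise ValueError("kernel_size must equal stride for exact upsampling")
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride = kernel_size, stride
        fan_in = c_in * kernel_size * kernel_size
        self.weight = self.add_param(
            "weight", he_uniform(rng, (c_in, c_out, self.k, self.k), fan_in, dtype))
        self.bias = self.add_param("bias", np.zeros(c_out, dtype=dtype)) if bias else None
        self._cache = None

    def forward(self, x):
        n, _, h, w = x.shape
        oh, ow = h * self.stride, w * self.stride
        xf = x.reshape(n, self.c_in, h * w)
        w2 = self.weight.value.reshape(self.c_in, -1)  # (c_in, c_out*k*k)
        cols = np.matmul(w2.T, xf)  # (n, c_out*k*k, h*w)
        pads = ((0, 0), (0, 0))
        y = col2im(cols, (n, self.c_out, oh, ow), self.k, self.k,
                   self.stride, 1, pads, (h, w))
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        self._cache = (xf, (n, h, w), (oh, ow))
        return y

    def backward(self, grad):
        xf, (n, h, w), _ = self._cache
        self._cache = None
        pads = ((0, 0), (0, 0))
        dcols, _ = im2col(grad, self.k, self.k, self.stride, 1, pads)
        w2 = self.weight.value.reshape(self.c_in, -1)
        self.weight.grad += np.einsum("ncl,nkl->ck", xf, dcols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        dx = np.matmul(w2, dcols)
        return dx.reshape(n, self.c_in, h, w)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.9, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.c = channels
        self.momentum, self.eps = momentum, eps
        self.gamma = self.add_param("gamma", np.ones(channels, dtype=dtype))
        self.beta = self.add_param("beta", np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv_std = self._cache
        self._cache = None
        n, _, h, w = grad.shape
        m = n * h * w
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not self.training:
            return g * inv_std[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gxsum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv_std[None, :, None, None] / m) * (m * g - gsum - xhat * gxsum)


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        mask, self._mask = self._mask, None
        return grad * mask


class MaxPool2d(Module):
    """2x2 max pooling; spatial dims must be even."""

    def __init__(self):
        super().__init__()
        self._cache = None

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        self._cache = (xr, y)
        return y

    def backward(self, grad):
        xr, y = self._cache
        self._cache = None
        mask = xr == y[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        g = mask * (grad[:, :, :, None, :, None] / counts)
        n, c, hh, _, ww, _ = xr.shape
        return g.reshape(n, c, hh * 2, ww * 2)


class BilinearUpsample(Module):
    """Fixed (non-learnable) bilinear upsampling by an integer factor."""

    _matrix_cache: dict[tuple[int, int], np.ndarray] = {}

    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor
        self._shapes = None

    @classmethod
    def _interp_matrix(cls, n_in: int, n_out: int) -> np.ndarray:
        key = (n_in, n_out)
        if key not in cls._matrix_cache:
            a = np.zeros((n_out, n_in))
            scale = n_in / n_out
            for o in range(n_out):
                src = (o + 0.5) * scale - 0.5
                i0 = int(np.floor(src))
                frac = src - i0
                a[o, min(max(i0, 0), n_in - 1)] += 1 - frac
                a[o, min(max(i0 + 1, 0), n_in - 1)] += frac
            cls._matrix_cache[key] = a
        return cls._matrix_cache[key]

    def forward(self, x):
        _, _, h, w = x.shape
        ah = self._interp_matrix(h, h * self.factor).astype(x.dtype)
        aw = self._interp_matrix(w, w * self.factor).astype(x.dtype)
        self._shapes = (ah, aw)
        y = np.einsum("nchw,oh->ncow", x, ah, optimize=True)
        return np.einsum("ncow,qw->ncoq", y, aw, optimize=True)

    def backward(self, grad):
        ah, aw = self._shapes
        self._shapes = None
        g = np.einsum("ncoq,qw->ncow", grad, aw, optimize=True)
        return np.einsum("ncow,oh->nchw", g, ah, optimize=True)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.modules = list(modules)
        for i, m in enumerate(self.modules):
            self.add_child(str(i), m)

    def forward(self, x):
        for m in self.modules:
            x = m.forward(x)
        return x

    def backward(self, grad):
        for m in reversed(self.modules):
            grad = m.backward(grad)
        return grad
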