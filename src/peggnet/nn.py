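"""Neural-network layers on top of :mod:`peggnet.autograd`.

Mirrors the small subset of a conventional layer API the architecture needs:
parameter registration, train/eval switching, state dicts, and the layers a
ConvNeXt-style classifier is assembled from.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import autograd as ag
from .autograd import Tensor

DEFAULT_DTYPE = np.float32

_rng = np.random.default_rng(0)


def set_rng(seed):
    """Reseed the generator used for parameter init and stochastic depth."""
    global _rng
    _rng = np.random.default_rng(seed)
    return _rng


def get_rng():
    return _rng


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DEFAULT_DTYPE), requires_grad=True)


def trunc_normal_(shape, std=0.02):
    """Truncated-normal draw (clipped at 2 std), the ConvNeXt init."""
    x = _rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std)


class Module:
    """Base class; discovers parameters/submodules from instance attributes."""

    def __init__(self):
        self.training = True

    # -- traversal -----------------------------------------------------
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    # -- modes ---------------------------------------------------------
    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization -------------------------------------------------
    def state_dict(self):
        state = OrderedDict((k, v.data.copy()) for k, v in self.named_parameters())
        for name, m in self._named_modules():
            for bname, buf in getattr(m, "_buffers", {}).items():
                state[f"{name}{bname}"] = buf.copy()
        return state

    def _named_modules(self, prefix=""):
        yield prefix, self
        for name, child in self._children():
            yield from child._named_modules(prefix + name + ".")

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        buffers = {
            f"{name}{bname}": (m, bname)
            for name, m in self._named_modules()
            for bname in getattr(m, "_buffers", {})
        }
        missing = set(params) | set(buffers)
        for key, value in state.items():
            if key in params:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                p.data = np.asarray(value, dtype=p.data.dtype)
                missing.discard(key)
            elif key in buffers:
                m, bname = buffers[key]
                m._buffers[bname] = np.asarray(value)
                missing.discard(key)
            else:
                raise KeyError(f"unexpected key {key!r} in state dict")
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")

    def astype(self, dtype):
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for m in self.modules():
            for k, v in getattr(m, "_buffers", {}).items():
                m._buffers[k] = v.astype(dtype)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def zero_(module):
    """Zero every parameter in place (test/oracle helper)."""
    for p in module.parameters():
        p.data[...] = 0
    return module


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(trunc_normal_((out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        return ag.linear(x, self.weight, self.bias)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, groups=1, bias=True):
        super().__init__()
        if in_channels % groups:
            raise ValueError("in_channels must be divisible by groups")
        k = kernel_size if isinstance(kernel_size, tuple) else (kernel_size,) * 2
        self.stride = stride
        self.padding = padding
        self.groups = groups
        self.weight = Parameter(
            trunc_normal_((out_channels, in_channels // groups, *k))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, groups=self.groups)


class LayerNorm(Module):
    """Layer normalization over the channel axis.

    ``data_format`` selects whether channels sit last (the in-block layout)
    or first (the NCHW layout between stages).
    """

    def __init__(self, dim, eps=1e-6, data_format="channels_last"):
        super().__init__()
        if data_format not in ("channels_last", "channels_first"):
            raise ValueError(data_format)
        self.eps = eps
        self.axis = -1 if data_format == "channels_last" else 1
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x):
        return ag.layer_norm(x, self.weight, self.bias, axis=self.axis, eps=self.eps)


class BatchNorm2d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self._buffers = {
            "running_mean": np.zeros(channels, dtype=DEFAULT_DTYPE),
            "running_var": np.ones(channels, dtype=DEFAULT_DTYPE),
        }

    def forward(self, x):
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu
            ).astype(self._buffers["running_mean"].dtype)
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var
            ).astype(self._buffers["running_var"].dtype)
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        shape = (1, -1, 1, 1)
        inv = (1.0 / np.sqrt(var + self.eps)).reshape(shape)
        xhat = ag.mul(ag.add(x, (-mu).reshape(shape)), inv)
        return ag.add(
            ag.mul(xhat, ag.reshape(self.weight, shape)),
            ag.reshape(self.bias, shape),
        )


class GELU(Module):
    def forward(self, x):
        return ag.gelu(x)


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ag.sigmoid(x)


class DropPath(Module):
    """Stochastic depth: drop the whole residual branch per sample."""

    def __init__(self, drop_prob=0.0):
        super().__init__()
        self.drop_prob = float(drop_prob)

    def forward(self, x):
        if not self.training or self.drop_prob == 0.0:
            return x
        keep = 1.0 - self.drop_prob
        n = x.shape[0]
        mask = (_rng.random(n) < keep).astype(x.data.dtype) / keep
        return ag.mul(x, mask.reshape((n,) + (1,) * (x.ndim - 1)))
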