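"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine carrying exactly the operations the
candling classifier needs: convolution (dense and depthwise), layer
normalization, affine maps, the GELU/ReLU/sigmoid nonlinearities, 2x
upsampling, concatenation, reductions, and the log-softmax/gather pieces the
loss is built from.  Every operation owns an analytic backward rule; the test
suite checks them against central finite differences.

Tensors wrap a numpy array and, when ``requires_grad`` is set (directly or
through a parent), record a closure that scatters the incoming gradient to
their parents.  ``Tensor.backward`` runs the closures in reverse topological
order.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "mul",
    "matmul",
    "linear",
    "conv2d",
    "layer_norm",
    "exp",
    "relu",
    "gelu",
    "sigmoid",
    "softmax",
    "log_softmax",
    "concat",
    "upsample2x",
    "mean",
    "power",
    "take_class",
    "global_avg_pool",
    "moveaxis",
    "reshape",
]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self):
        return self.data.item()

    def numpy(self):
        return self.data

    # -- autograd ------------------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self):
        return _sum_all(self)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / arithmetic


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a, b):
    a = as_tensor(a)
    if not isinstance(b, Tensor):
        b_arr = np.asarray(b, dtype=a.data.dtype)
        out_data = a.data * b_arr

        def backward_const(g):
            a._accumulate(_unbroadcast(g * b_arr, a.data.shape))

        return Tensor(out_data, parents=(a,), backward=backward_const)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def power(x, exponent):
    """x ** exponent for a fixed real exponent, with x >= 0 assumed."""
    x = as_tensor(x)
    out_data = np.power(x.data, exponent)

    def backward(g):
        base = np.where(x.data > 0, x.data, 1.0)
        x._accumulate(g * exponent * np.power(base, exponent - 1.0) * (x.data > 0))

    return Tensor(out_data, parents=(x,), backward=backward)


def _sum_all(x):
    x = as_tensor(x)
    out_data = np.asarray(x.data.sum())

    def backward(g):
        x._accumulate(np.broadcast_to(g, x.data.shape))

    return Tensor(out_data, parents=(x,), backward=backward)


def mean(x, axis=None, keepdims=False):
    x = as_tensor(x)
    out_data = x.data.mean(axis=axis, keepdims=keepdims)
    n = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in np.atleast_1d(axis)]
    )

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.data.shape) / n)

    return Tensor(out_data, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# nonlinearities


def exp(x):
    x = as_tensor(x)
    out_data = np.exp(x.data)

    def backward(g):
        x._accumulate(g * out_data)

    return Tensor(out_data, parents=(x,), backward=backward)


def relu(x):
    x = as_tensor(x)
    out_data = np.maximum(x.data, 0)

    def backward(g):
        x._accumulate(g * (x.data > 0))

    return Tensor(out_data, parents=(x,), backward=backward)


def sigmoid(x):
    x = as_tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(x,), backward=backward)


def gelu(x):
    """Exact (erf-based) GELU."""
    x = as_tensor(x)
    cdf = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))
    out_data = x.data * cdf

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data * x.data)
        x._accumulate(g * (cdf + x.data * pdf))

    return Tensor(out_data, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# linear algebra


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def linear(x, weight, bias=None):
    """y[..., o] = x[..., i] W[o, i] + b[o]."""
    x, weight = as_tensor(x), as_tensor(weight)
    out_data = x.data @ weight.data.T
    if bias is not None:
        bias = as_tensor(bias)
        out_data = out_data + bias.data
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g @ weight.data)
        if weight.requires_grad:
            gw = np.tensordot(
                g, x.data, axes=(tuple(range(g.ndim - 1)), tuple(range(g.ndim - 1)))
            )
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=tuple(range(g.ndim - 1))))

    return Tensor(out_data, parents=parents, backward=backward)


# ---------------------------------------------------------------------------
# convolution


def conv2d(x, weight, bias=None, stride=1, padding=0, groups=1):
    """2-D cross-correlation over NCHW input.

    ``weight`` has shape (C_out, C_in/groups, kh, kw).  Only the dense
    (groups == 1) and depthwise (groups == C_in == C_out) cases are
    implemented; they are the only ones the architecture uses.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w = x.data.shape
    co, cg, kh, kw = weight.data.shape
    s = int(stride)
    p = int(padding)
    if groups == 1:
        if cg != c:
            raise ValueError(f"weight expects {cg} input channels, got {c}")
        depthwise = False
    elif groups == c and co == c and cg == 1:
        depthwise = True
    else:
        raise NotImplementedError("conv2d supports groups=1 or depthwise only")
    ho = (h + 2 * p - kh) // s + 1
    wo = (w + 2 * p - kw) // s + 1
    if ho <= 0 or wo <= 0:
        raise ValueError("convolution output would be empty")
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        if p
        else x.data
    )
    wd = weight.data
    out_data = np.zeros((n, co, ho, wo), dtype=x.data.dtype)
    # accumulate one kernel offset at a time; keeps memory at O(output)
    for i in range(kh):
        for j in range(kw):
            xv = xp[:, :, i : i + ho * s : s, j : j + wo * s : s]
            if depthwise:
                out_data += wd[:, 0, i, j].reshape(1, -1, 1, 1) * xv
            else:
                out_data += np.einsum(
                    "oc,nchw->nohw", wd[:, :, i, j], xv, optimize=True
                )
    if bias is not None:
        bias = as_tensor(bias)
        out_data += bias.data.reshape(1, -1, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if weight.requires_grad:
            gw = np.zeros_like(wd)
        need_gx = x.requires_grad
        if need_gx:
            gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                xv = xp[:, :, i : i + ho * s : s, j : j + wo * s : s]
                if weight.requires_grad:
                    if depthwise:
                        gw[:, 0, i, j] = np.einsum(
                            "nchw,nchw->c", g, xv, optimize=True
                        )
                    else:
                        gw[:, :, i, j] = np.einsum(
                            "nohw,nchw->oc", g, xv, optimize=True
                        )
                if need_gx:
                    if depthwise:
                        gxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += (
                            wd[:, 0, i, j].reshape(1, -1, 1, 1) * g
                        )
                    else:
                        gxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += np.einsum(
                            "oc,nohw->nchw", wd[:, :, i, j], g, optimize=True
                        )
        if weight.requires_grad:
            weight._accumulate(gw)
        if need_gx:
            x._accumulate(gxp[:, :, p : p + h, p : p + w] if p else gxp)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor(out_data, parents=parents, backward=backward)


# ---------------------------------------------------------------------------
# normalization


def layer_norm(x, weight, bias, axis=-1, eps=1e-6):
    """Normalize over a single axis, then scale and shift along it."""
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    ax = axis % x.data.ndim
    mu = x.data.mean(axis=ax, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=ax, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    bshape = [1] * x.data.ndim
    bshape[ax] = x.data.shape[ax]
    wb = weight.data.reshape(bshape)
    out_data = xhat * wb + bias.data.reshape(bshape)
    nred = tuple(i for i in range(x.data.ndim) if i != ax)

    def backward(g):
        if weight.requires_grad:
            weight._accumulate((g * xhat).sum(axis=nred))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=nred))
        if x.requires_grad:
            gh = g * wb
            m1 = gh.mean(axis=ax, keepdims=True)
            m2 = (gh * xhat).mean(axis=ax, keepdims=True)
            x._accumulate(inv * (gh - m1 - xhat * m2))

    return Tensor(out_data, parents=(x, weight, bias), backward=backward)


# ---------------------------------------------------------------------------
# shape manipulation


def moveaxis(x, src, dst):
    x = as_tensor(x)
    out_data = np.moveaxis(x.data, src, dst)

    def backward(g):
        x._accumulate(np.moveaxis(g, dst, src))

    return Tensor(out_data, parents=(x,), backward=backward)


def reshape(x, shape):
    x = as_tensor(x)
    out_data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(x.data.shape))

    return Tensor(out_data, parents=(x,), backward=backward)


def concat(tensors, axis=1):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def _interp_weights(n_out, n_in, mode):
    """Per-output (index0, index1, weight0, weight1) for 2x-style resampling."""
    o = np.arange(n_out)
    if mode == "nearest":
        i0 = np.clip((o * n_in) // n_out, 0, n_in - 1)
        return i0, i0, np.ones(n_out), np.zeros(n_out)
    # bilinear, half-pixel centers (align_corners=False)
    src = (o + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    return i0, i1, 1.0 - w1, w1


def upsample2x(x, mode="bilinear"):
    """Double the spatial extent of an NCHW map (nearest or bilinear)."""
    if mode not in ("nearest", "bilinear"):
        raise ValueError(f"unknown upsample mode {mode!r}")
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    hi0, hi1, hw0, hw1 = _interp_weights(2 * h, h, mode)
    wi0, wi1, ww0, ww1 = _interp_weights(2 * w, w, mode)
    hw0c = hw0[:, None]
    hw1c = hw1[:, None]
    xh = x.data[:, :, hi0, :] * hw0c + x.data[:, :, hi1, :] * hw1c
    out_data = xh[:, :, :, wi0] * ww0 + xh[:, :, :, wi1] * ww1

    def backward(g):
        gh = np.zeros((n, c, 2 * h, w), dtype=g.dtype)
        np.add.at(gh, (slice(None), slice(None), slice(None), wi0), g * ww0)
        np.add.at(gh, (slice(None), slice(None), slice(None), wi1), g * ww1)
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), hi0, slice(None)), gh * hw0c)
        np.add.at(gx, (slice(None), slice(None), hi1, slice(None)), gh * hw1c)
        x._accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=backward)


def global_avg_pool(x):
    """NCHW -> NC mean over the spatial extent."""
    return mean(x, axis=(2, 3))


# ---------------------------------------------------------------------------
# classification head pieces


def log_softmax(x, axis=-1):
    x = as_tensor(x)
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse

    def backward(g):
        sm = np.exp(out_data)
        x._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

    return Tensor(out_data, parents=(x,), backward=backward)


def softmax(x, axis=-1):
    ls = log_softmax(x, axis=axis)
    out_data = np.exp(ls.data)

    def backward(g):
        ls._accumulate(g * out_data)

    return Tensor(out_data, parents=(ls,), backward=backward)


def take_class(x, labels):
    """Select x[i, labels[i]] from an (N, K) tensor -> (N,) tensor."""
    x = as_tensor(x)
    labels = np.asarray(labels, dtype=int)
    idx = np.arange(x.data.shape[0])
    out_data = x.data[idx, labels]

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[idx, labels] = g
        x._accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=backward)
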