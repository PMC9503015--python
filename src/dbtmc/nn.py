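"""A small reverse-mode autodiff framework for CNN classifiers.

Implements exactly what the study's architectures need — convolution
(with groups), batch normalization, max/global-average pooling, linear
layers, ReLU, dropout, residual addition and channel concatenation —
on numpy arrays (float32 by default), with an SGD + momentum optimizer
and cross-entropy loss.  It is not a general deep-learning library;
it is the minimal engine behind :mod:`dbtmc.models`.

Design notes: convolutions use an im2col/col2im formulation backed by
BLAS matmul; max-pool backward scatters through recorded argmax
indices; all parameter initialization draws from a generator passed to
the layer constructors, so two builds from the same seed are
bit-identical.
"""

from __future__ import annotations

import pickle
from pathlib import Path

import numpy as np

from dbtmc.exceptions import ShapeError


# ---------------------------------------------------------------------------
# autodiff core

class Tensor:
    """An array node in the backward graph."""

    __slots__ = ("data", "grad", "parents", "bw", "requires_grad", "_grad_shared")

    def __init__(self, data, parents=(), bw=None, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self.parents = parents
        self.bw = bw  # closure: grad_out -> None (accumulates into parents)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._grad_shared = False

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        # first contribution: adopt the array (closures hand over fresh
        # buffers except add/concat, which mark sharing); later
        # contributions add, copying first if the buffer is shared
        if self.grad is None:
            self.grad = g if g.dtype == self.data.dtype else g.astype(self.data.dtype)
        elif self._grad_shared:
            self.grad = self.grad + g
            self._grad_shared = False
        else:
            self.grad += g

    def backward(self, grad=None):
        """Reverse-mode sweep from this node (scalar unless grad given)."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, self.data.dtype)
        )
        self._grad_shared = grad is not None
        for t in reversed(topo):
            if t.bw is not None:
                t.bw(t.grad)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


# ---------------------------------------------------------------------------
# functional ops

def _pad(x, p):
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _conv_out_size(h, k, s, p):
    return (h + 2 * p - k) // s + 1


def conv2d(x: Tensor, w: Parameter, b: Parameter, stride=1, padding=0, groups=1,
           name="conv") -> Tensor:
    """Grouped 2-D convolution, NCHW layout, weight (Cout, Cin/g, kh, kw)."""
    n, c, h, wd = x.data.shape
    cout, cin_g, kh, kw = w.data.shape
    ho = _conv_out_size(h, kh, stride, padding)
    wo = _conv_out_size(wd, kw, stride, padding)
    if ho <= 0 or wo <= 0:
        raise ShapeError(
            f"layer {name!r}: output extent {ho}x{wo} non-positive for input {h}x{wd}"
        )
    xp = _pad(x.data, padding)
    L = ho * wo
    # build im2col directly in (c*kh*kw, n*L) layout: each group one sgemm
    xt = xp.transpose(1, 0, 2, 3)  # (c, n, Hp, Wp) view
    cols6 = np.empty((c, kh, kw, n, ho, wo), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            cols6[:, i, j] = xt[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride]
    cols2 = cols6.reshape(c * kh * kw, n * L)
    wmat = w.data.reshape(cout, cin_g * kh * kw)
    cpg_in = c // groups * kh * kw
    cpg_out = cout // groups
    out2 = np.empty((cout, n * L), dtype=x.data.dtype)
    for g in range(groups):
        out2[g * cpg_out : (g + 1) * cpg_out] = (
            wmat[g * cpg_out : (g + 1) * cpg_out] @ cols2[g * cpg_in : (g + 1) * cpg_in]
        )
    out2 += b.data[:, None]
    out = np.ascontiguousarray(out2.reshape(cout, n, ho, wo).transpose(1, 0, 2, 3))

    def bw(grad):
        if b.requires_grad:
            b._accumulate(grad.sum(axis=(0, 2, 3)))
        gt = np.ascontiguousarray(grad.transpose(1, 0, 2, 3)).reshape(cout, n * L)
        dw = np.empty((cout, cin_g * kh * kw), dtype=w.data.dtype)
        dcols2 = np.empty_like(cols2) if x.requires_grad else None
        for g in range(groups):
            go = gt[g * cpg_out : (g + 1) * cpg_out]
            dw[g * cpg_out : (g + 1) * cpg_out] = (
                go @ cols2[g * cpg_in : (g + 1) * cpg_in].T
            )
            if dcols2 is not None:
                dcols2[g * cpg_in : (g + 1) * cpg_in] = (
                    wmat[g * cpg_out : (g + 1) * cpg_out].T @ go
                )
        if w.requires_grad:
            w._accumulate(dw.reshape(w.data.shape))
        if x.requires_grad:
            dcv = dcols2.reshape(c, kh, kw, n, ho, wo)
            dxp = np.zeros(xp.shape, dtype=x.data.dtype)
            dxt = dxp.transpose(1, 0, 2, 3)
            for i in range(kh):
                for j in range(kw):
                    dxt[:, :, i : i + ho * stride : stride,
                        j : j + wo * stride : stride] += dcv[:, i, j]
            dx = dxp if padding == 0 else dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dx)

    return Tensor(out, (x, w, b), bw)


def max_pool2d(x: Tensor, kernel=3, stride=2, name="pool") -> Tensor:
    n, c, h, w = x.data.shape
    ho = _conv_out_size(h, kernel, stride, 0)
    wo = _conv_out_size(w, kernel, stride, 0)
    if ho <= 0 or wo <= 0:
        raise ShapeError(
            f"layer {name!r}: output extent {ho}x{wo} non-positive for input {h}x{w}"
        )
    s0, s1, s2, s3 = x.data.strides
    win = np.lib.stride_tricks.as_strided(
        x.data,
        shape=(n, c, ho, wo, kernel, kernel),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    ).reshape(n, c, ho, wo, kernel * kernel)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bw(grad):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        ni, ci, ri, qi = np.indices(idx.shape, sparse=False)
        rr = ri * stride + idx // kernel
        cc = qi * stride + idx % kernel
        np.add.at(dx, (ni, ci, rr, cc), grad)
        x._accumulate(dx)

    return Tensor(out, (x,), bw)


def _accumulate_shared(t: Tensor, g) -> None:
    """Accumulate a gradient that views/shares another buffer."""
    t._accumulate(g)
    t._grad_shared = True


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def bw(grad):
        if x.requires_grad:
            _accumulate_shared(
                x, np.broadcast_to(grad[:, :, None, None] / (h * w), x.data.shape)
            )

    return Tensor(out, (x,), bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def bw(grad):
        if x.requires_grad:
            x._accumulate(grad * mask)

    return Tensor(out, (x,), bw)


def linear(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    out = x.data @ w.data.T + b.data

    def bw(grad):
        if b.requires_grad:
            b._accumulate(grad.sum(axis=0))
        if w.requires_grad:
            w._accumulate(grad.T @ x.data)
        if x.requires_grad:
            x._accumulate(grad @ w.data)

    return Tensor(out, (x, w, b), bw)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def bw(grad):
        if a.requires_grad:
            _accumulate_shared(a, grad)
        if b.requires_grad:
            _accumulate_shared(b, grad)

    return Tensor(out, (a, b), bw)


def concat(tensors: list[Tensor], axis=1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(grad):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(start, start + s)
                _accumulate_shared(t, grad[tuple(sl)])
            start += s

    return Tensor(out, tuple(tensors), bw)


def flatten(x: Tensor) -> Tensor:
    n = x.data.shape[0]
    out = x.data.reshape(n, -1)

    def bw(grad):
        if x.requires_grad:
            _accumulate_shared(x, grad.reshape(x.data.shape))

    return Tensor(out, (x,), bw)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; labels are integer class indices."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-30)).mean()

    def bw(grad):
        if logits.requires_grad:
            d = p.copy()
            d[np.arange(n), labels] -= 1.0
            logits._accumulate(grad * d / n)

    return Tensor(np.asarray(loss, dtype=logits.data.dtype), (logits,), bw)


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# modules

class Module:
    """Base class: parameter collection and train/eval mode."""

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        yield m
                        yield from m.modules()

    def parameters(self) -> list[Parameter]:
        params = []
        for m in [self, *self.modules()]:
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    params.append(v)
        return params

    def set_training(self, flag: bool):
        for m in [self, *self.modules()]:
            if hasattr(m, "training"):
                m.training = flag

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def describe(self) -> dict:
        return {"kind": type(self).__name__.lower()}

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()] + [
            s.copy() for s in getattr(self, "_buffers", [])
        ]

    def save(self, path: str | Path):
        blobs = [p.data for p in self.parameters()]
        for m in [self, *self.modules()]:
            if isinstance(m, BatchNorm2d):
                blobs += [m.running_mean, m.running_var]
        with open(path, "wb") as fh:
            pickle.dump(blobs, fh)

    def load(self, path: str | Path):
        with open(path, "rb") as fh:
            blobs = pickle.load(fh)
        params = self.parameters()
        for p, b in zip(params, blobs):
            p.data = np.asarray(b, dtype=p.data.dtype)
        i = len(params)
        for m in [self, *self.modules()]:
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(blobs[i])
                m.running_var = np.asarray(blobs[i + 1])
                i += 2


def _glorot_init(rng, shape, fan_in, fan_out, dtype=np.float32):
    # Glorot/Xavier uniform: keeps activation scale bounded through deep
    # fc stacks, which SGDM needs at small epoch budgets
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape).astype(dtype)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel, stride=1, padding=0, groups=1,
                 rng=None, name="conv"):
        rng = rng or np.random.default_rng()
        fan_in = cin // groups * kernel * kernel
        fan_out = cout // groups * kernel * kernel
        self.w = Parameter(
            _glorot_init(rng, (cout, cin // groups, kernel, kernel), fan_in, fan_out)
        )
        self.b = Parameter(np.zeros(cout, dtype=np.float32))
        self.stride, self.padding, self.groups = stride, padding, groups
        self.kernel, self.cin, self.cout, self.name = kernel, cin, cout, name

    def __call__(self, x):
        return conv2d(x, self.w, self.b, self.stride, self.padding, self.groups, self.name)

    def describe(self):
        return {
            "kind": "groupconv" if self.groups > 1 else "conv",
            "name": self.name, "in": self.cin, "out": self.cout,
            "kernel": self.kernel, "stride": self.stride,
            "padding": self.padding, "groups": self.groups,
        }


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5, name="norm"):
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps, self.training, self.name = momentum, eps, True, name

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        training = self.training
        gamma = self.gamma

        def bw(grad):
            if gamma.requires_grad:
                gamma._accumulate((grad * xhat).sum(axis=(0, 2, 3)))
            if self.beta.requires_grad:
                self.beta._accumulate(grad.sum(axis=(0, 2, 3)))
            if not x.requires_grad:
                return
            gi = grad * gamma.data[None, :, None, None]
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                dxhat_sum = gi.sum(axis=(0, 2, 3))
                dxhat_xhat = (gi * xhat).sum(axis=(0, 2, 3))
                dx = (
                    inv[None, :, None, None]
                    * (gi - (dxhat_sum[None, :, None, None]
                             + xhat * dxhat_xhat[None, :, None, None]) / m)
                )
            else:
                dx = gi * inv[None, :, None, None]
            x._accumulate(dx)

        return Tensor(out, (x, self.gamma, self.beta), bw)

    def describe(self):
        return {"kind": "batchnorm", "name": self.name, "channels": len(self.running_mean)}


class MaxPool2d(Module):
    def __init__(self, kernel=3, stride=2, name="pool"):
        self.kernel, self.stride, self.name = kernel, stride, name

    def __call__(self, x):
        return max_pool2d(x, self.kernel, self.stride, self.name)

    def describe(self):
        return {"kind": "maxpool", "name": self.name, "kernel": self.kernel,
                "stride": self.stride, "padding": 0}


class GlobalAvgPool(Module):
    def __call__(self, x):
        return global_avg_pool(x)

    def describe(self):
        return {"kind": "globalavgpool"}


class ReLU(Module):
    def __call__(self, x):
        return relu(x)

    def describe(self):
        return {"kind": "relu"}


class Dropout(Module):
    def __init__(self, p=0.5, rng=None, name="drop"):
        self.p, self.training, self.name = p, True, name
        self.rng = rng or np.random.default_rng()

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        mask = mask.astype(x.data.dtype)
        out = x.data * mask

        def bw(grad):
            if x.requires_grad:
                x._accumulate(grad * mask)

        return Tensor(out, (x,), bw)

    def describe(self):
        return {"kind": "dropout", "name": self.name, "p": self.p}


class Linear(Module):
    def __init__(self, fin, fout, rng=None, name="fc"):
        rng = rng or np.random.default_rng()
        self.w = Parameter(_glorot_init(rng, (fout, fin), fin, fout))
        self.b = Parameter(np.zeros(fout, dtype=np.float32))
        self.fin, self.fout, self.name = fin, fout, name

    def __call__(self, x):
        return linear(x, self.w, self.b)

    def describe(self):
        return {"kind": "fc", "name": self.name, "in": self.fin, "out": self.fout}


class Flatten(Module):
    def __call__(self, x):
        return flatten(x)

    def describe(self):
        return {"kind": "flatten"}


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def __call__(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def describe_layers(self) -> list[dict]:
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out.extend(layer.describe_layers())
            else:
                out.append(layer.describe())
        return out


# ---------------------------------------------------------------------------
# optimization

class SGD:
    """Stochastic gradient descent with momentum and L2 weight decay."""

    def __init__(self, params: list[Parameter], lr=1e-3, momentum=0.9, weight_decay=0.0):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            if self.weight_decay:
                v += self.weight_decay * p.data
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
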