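"""Minimal reverse-mode automatic differentiation over numpy arrays.

This engine exists because the segmentation/evaluation networks and the
adversarial training loop are trained on CPU with nothing heavier than
numpy available.  It implements exactly the operations those networks
need: 2-D convolution (im2col), 2x2 average pooling, nearest-neighbour
upsampling, channel concatenation, ReLU/sigmoid/softmax, global average
pooling, a dense layer and the elementwise/reduction arithmetic used by
the loss functions.

Conventions
-----------
* Image batches are NCHW float arrays; dtype is preserved through the
  graph (networks default to float32 for speed, float64 is used where
  tests need tight tolerances).
* ``Tensor.backward()`` may only be called on a scalar.
* ``requires_grad`` is captured when an operation node is *created*:
  a graph built while a parameter is temporarily frozen never writes
  gradients into that parameter, even if ``backward()`` runs after the
  parameter is unfrozen.  The adversarial losses rely on this.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "add", "sub", "mul", "div", "neg", "log",
    "clamp", "relu", "sigmoid", "softmax_channels", "tensor_sum", "mean",
    "concat", "conv2d", "avg_pool2", "upsample2", "global_avg_pool",
    "linear", "SGD", "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:                      # iterative DFS: deep loss graphs
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, as_tensor(other))

    def __rsub__(self, other):
        return sub(as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise arithmetic --------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a_req, b_req = a.requires_grad, b.requires_grad

    def bw(g):
        if a_req:
            a._accumulate(_unbroadcast(g, a.shape))
        if b_req:
            b._accumulate(_unbroadcast(g, b.shape))

    return Tensor(a.data + b.data, parents=(a, b), backward=bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    a_req, b_req = a.requires_grad, b.requires_grad

    def bw(g):
        if a_req:
            a._accumulate(_unbroadcast(g, a.shape))
        if b_req:
            b._accumulate(_unbroadcast(-g, b.shape))

    return Tensor(a.data - b.data, parents=(a, b), backward=bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a_req, b_req = a.requires_grad, b.requires_grad

    def bw(g):
        if a_req:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b_req:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(a.data * b.data, parents=(a, b), backward=bw)


def div(a: Tensor, b: Tensor) -> Tensor:
    a_req, b_req = a.requires_grad, b.requires_grad

    def bw(g):
        if a_req:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b_req:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    return Tensor(a.data / b.data, parents=(a, b), backward=bw)


def neg(a: Tensor) -> Tensor:
    a_req = a.requires_grad

    def bw(g):
        if a_req:
            a._accumulate(-g)

    return Tensor(-a.data, parents=(a,), backward=bw)


def log(a: Tensor) -> Tensor:
    a_req = a.requires_grad

    def bw(g):
        if a_req:
            a._accumulate(g / a.data)

    return Tensor(np.log(a.data), parents=(a,), backward=bw)


def clamp(a: Tensor, lo: float, hi: float) -> Tensor:
    a_req = a.requires_grad
    inside = (a.data > lo) & (a.data < hi)

    def bw(g):
        if a_req:
            a._accumulate(g * inside)

    return Tensor(np.clip(a.data, lo, hi), parents=(a,), backward=bw)


# -- nonlinearities -----------------------------------------------------

def relu(a: Tensor) -> Tensor:
    a_req = a.requires_grad
    pos = a.data > 0

    def bw(g):
        if a_req:
            a._accumulate(g * pos)

    return Tensor(a.data * pos, parents=(a,), backward=bw)


def sigmoid(a: Tensor) -> Tensor:
    a_req = a.requires_grad
    s = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        if a_req:
            a._accumulate(g * s * (1.0 - s))

    return Tensor(s, parents=(a,), backward=bw)


def softmax_channels(a: Tensor) -> Tensor:
    """Softmax along axis 1 of an NCHW tensor."""
    a_req = a.requires_grad
    z = a.data - a.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=1, keepdims=True)

    def bw(g):
        if a_req:
            dot = (g * s).sum(axis=1, keepdims=True)
            a._accumulate(s * (g - dot))

    return Tensor(s, parents=(a,), backward=bw)


# -- reductions ---------------------------------------------------------

def tensor_sum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a_req = a.requires_grad

    def bw(g):
        if not a_req:
            return
        g = np.asarray(g)
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape))
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for ax in sorted(ax % a.ndim for ax in axes):
                    g = np.expand_dims(g, ax)
            a._accumulate(np.broadcast_to(g, a.shape))

    return Tensor(a.data.sum(axis=axis, keepdims=keepdims),
                  parents=(a,), backward=bw)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tensor_sum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


# -- structural ops -----------------------------------------------------

def concat(tensors: list, axis: int = 1) -> Tensor:
    reqs = [t.requires_grad for t in tensors]
    splits = np.cumsum([t.shape[axis] for t in tensors])[:-1]

    def bw(g):
        pieces = np.split(g, splits, axis=axis)
        for t, req, piece in zip(tensors, reqs, pieces):
            if req:
                t._accumulate(piece)

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bw)


# -- convolution and pooling -------------------------------------------

def _shift_add(dst, src, dy, dx):
    """dst[..., y, x] += src[..., y+dy, x+dx] over the valid overlap."""
    h, w = dst.shape[2], dst.shape[3]
    dst[:, :, max(0, -dy):h - max(0, dy), max(0, -dx):w - max(0, dx)] += \
        src[:, :, max(0, dy):h - max(0, -dy), max(0, dx):w - max(0, -dx)]


def _conv1x1(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1x1 convolution = batched channel-mixing matmul; no copies."""
    n, c, h, wid = x.shape
    f = w.shape[0]
    x_req, w_req, b_req = x.requires_grad, w.requires_grad, b.requires_grad
    w2 = w.data.reshape(f, c)
    xr = x.data.reshape(n, c, h * wid)
    out_data = np.matmul(w2, xr).reshape(n, f, h, wid) \
        + b.data[None, :, None, None]

    def bw(g):
        gr = g.reshape(n, f, h * wid)
        if w_req:
            dw = np.matmul(gr, xr.transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(dw.reshape(w.shape))
        if b_req:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x_req:
            x._accumulate(np.matmul(w2.T, gr).reshape(x.shape))

    return Tensor(out_data, parents=(x, w, b), backward=bw)


def _conv_stride1(x: Tensor, w: Tensor, b: Tensor, padding: int) -> Tensor:
    """Same-size stride-1 convolution by shift-and-add.

    Each kernel tap is one batched channel-mixing matmul whose result is
    added into the output at the tap's spatial offset; no im2col matrix
    or input gather is ever materialized, which keeps the op memory-bound
    on the *output* (small channel counts) rather than the input.
    """
    n, c, h, wid = x.shape
    f, _, kh, kw = w.shape
    x_req, w_req, b_req = x.requires_grad, w.requires_grad, b.requires_grad
    xr = x.data.reshape(n, c, h * wid)
    out = np.zeros((n, f, h, wid), dtype=np.result_type(x.data, w.data))
    offs = [(i, j, i - padding, j - padding)
            for i in range(kh) for j in range(kw)]
    for i, j, di, dj in offs:
        y = np.matmul(w.data[:, :, i, j], xr).reshape(n, f, h, wid)
        _shift_add(out, y, di, dj)
    out_data = out + b.data[None, :, None, None]

    def bw(g):
        gr = g.reshape(n, f, h * wid)
        if w_req:
            dw = np.empty_like(w.data)
            hh, ww = h, wid
            for i, j, di, dj in offs:
                gv = g[:, :, max(0, -di):hh - max(0, di),
                       max(0, -dj):ww - max(0, dj)]
                xv = x.data[:, :, max(0, di):hh - max(0, -di),
                            max(0, dj):ww - max(0, -dj)]
                dw[:, :, i, j] = np.einsum("nfyx,ncyx->fc", gv, xv,
                                           optimize=True)
            w._accumulate(dw)
        if b_req:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x_req:
            dx = np.zeros_like(x.data)
            for i, j, di, dj in offs:
                d = np.matmul(w.data[:, :, i, j].T, gr).reshape(n, c, h, wid)
                _shift_add(dx, d, -di, -dj)
            x._accumulate(dx)

    return Tensor(out_data, parents=(x, w, b), backward=bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1,
           padding: int = 1) -> Tensor:
    """NCHW convolution; w is (F, C, kh, kw), b is (F,).

    Dispatches to a batched-matmul path for 1x1 kernels and a
    shift-and-add path for same-size stride-1 kernels; strided
    convolutions (used only by the small evaluation network) go through
    an explicit per-tap gather.
    """
    n, c, h, wid = x.shape
    f, cin, kh, kw = w.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cin}")
    if kh == 1 and kw == 1 and stride == 1 and padding == 0:
        return _conv1x1(x, w, b)
    if stride == 1 and kh == 2 * padding + 1 and kw == 2 * padding + 1:
        return _conv_stride1(x, w, b, padding)

    x_req, w_req, b_req = x.requires_grad, w.requires_grad, b.requires_grad
    xp = np.zeros((n, c, h + 2 * padding, wid + 2 * padding),
                  dtype=x.data.dtype)
    xp[:, :, padding:padding + h, padding:padding + wid] = x.data
    ho = (xp.shape[2] - kh) // stride + 1
    wo = (xp.shape[3] - kw) // stride + 1
    taps = [(i, j) for i in range(kh) for j in range(kw)]

    # one contiguous (c, n*ho*wo) matrix per kernel tap; reused for dW
    tapmats = [np.ascontiguousarray(
        xp[:, :, i:i + stride * ho:stride,
           j:j + stride * wo:stride].transpose(1, 0, 2, 3)
    ).reshape(c, n * ho * wo) for i, j in taps]

    acc = np.zeros((f, n * ho * wo), dtype=xp.dtype)
    for (i, j), tm in zip(taps, tapmats):
        acc += w.data[:, :, i, j] @ tm
    out_data = acc.reshape(f, n, ho, wo).transpose(1, 0, 2, 3) \
        + b.data[None, :, None, None]

    def bw(g):
        gr = np.ascontiguousarray(
            g.transpose(1, 0, 2, 3)).reshape(f, n * ho * wo)
        if w_req:
            dw = np.empty_like(w.data)
            for (i, j), tm in zip(taps, tapmats):
                dw[:, :, i, j] = gr @ tm.T
            w._accumulate(dw)
        if b_req:
            b._accumulate(gr.sum(axis=1))
        if x_req:
            dxp = np.zeros_like(xp)
            for i, j in taps:
                dtap = (w.data[:, :, i, j].T @ gr).reshape(c, n, ho, wo)
                dxp[:, :, i:i + stride * ho:stride,
                    j:j + stride * wo:stride] += dtap.transpose(1, 0, 2, 3)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return Tensor(out_data, parents=(x, w, b), backward=bw)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2; H and W must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2 needs even spatial dims, got {h}x{w}")
    x_req = x.requires_grad

    def bw(g):
        if x_req:
            x._accumulate(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0)

    return Tensor(x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5)),
                  parents=(x,), backward=bw)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    x_req = x.requires_grad

    def bw(g):
        if x_req:
            n, c, h2, w2 = g.shape
            x._accumulate(
                g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3),
                  parents=(x,), backward=bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> NC mean over the spatial grid."""
    n, c, h, w = x.shape
    x_req = x.requires_grad

    def bw(g):
        if x_req:
            x._accumulate(np.broadcast_to(
                g[:, :, None, None] / (h * w), x.shape))

    return Tensor(x.data.mean(axis=(2, 3)), parents=(x,), backward=bw)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x: (N, C), w: (C, F), b: (F,)."""
    x_req, w_req, b_req = x.requires_grad, w.requires_grad, b.requires_grad

    def bw(g):
        if w_req:
            w._accumulate(x.data.T @ g)
        if b_req:
            b._accumulate(g.sum(axis=0))
        if x_req:
            x._accumulate(g @ w.data.T)

    return Tensor(x.data @ w.data + b.data, parents=(x, w, b), backward=bw)


# -- optimizers ---------------------------------------------------------

class SGD:
    """Plain SGD with L2 weight decay folded into the gradient."""

    def __init__(self, params: list, lr: float, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)

    def step(self):
        for p in self.params:
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            p.data -= self.lr * g

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params: list, lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
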