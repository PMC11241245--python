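"""A minimal reverse-mode automatic-differentiation engine on numpy arrays.

This is the numerical substrate for the convolutional classifier: a
:class:`Tensor` wraps an ndarray and records, per operation, a closure that
accumulates gradients into its parents.  ``backward()`` runs a topological
sort and applies the closures in reverse order.  Only the operations the
network needs are implemented: 2-D (grouped-as-depthwise) convolution via
im2col, dense layers, batch normalization, the SiLU/sigmoid/ReLU
nonlinearities, reductions, concatenation, dropout and a fused
softmax-cross-entropy.

Convolutions are lowered to BLAS matrix multiplies through
``sliding_window_view`` so a CPU forward/backward pass stays practical at
desk scale.  Inference can run without graph construction under
:func:`no_grad`.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Disable graph construction (fast inference path)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _as_float(data) -> np.ndarray:
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    return arr


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = _as_float(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- plumbing -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None) -> None:
        """Reverse-mode sweep from this tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _wrap(-1.0)))

    def __neg__(self):
        return mul(self, _wrap(-1.0))

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True)
    else:
        t.grad += g


def _make(data, parents, backward) -> Tensor:
    if grad_enabled() and any(p.requires_grad or p._parents for p in parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == tuple(shape):
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise and linear algebra


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.shape))
        _accumulate(b, _unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    return _make(out_data, (a, b), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x (N, D) @ w (D, M) + b (M,)."""
    out = matmul(x, w)
    if b is not None:
        out = add(out, b)
    return out


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0)

    def backward(g):
        _accumulate(x, g * (x.data > 0))

    return _make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        _accumulate(x, g * s * (1.0 - s))

    return _make(s, (x,), backward)


def silu(x: Tensor) -> Tensor:
    """x * sigmoid(x) (the swish activation)."""
    s = 1.0 / (1.0 + np.exp(-x.data))
    out_data = x.data * s

    def backward(g):
        _accumulate(x, g * (s * (1.0 + x.data * (1.0 - s))))

    return _make(out_data, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    out_data = x.data.reshape(shape)

    def backward(g):
        _accumulate(x, g.reshape(x.shape))

    return _make(out_data, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


def reduce_sum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            _accumulate(x, np.broadcast_to(g, x.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accumulate(x, np.broadcast_to(g, x.shape).copy())

    return _make(out_data, (x,), backward)


def reduce_mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    axes = axis if axis is not None else tuple(range(x.data.ndim))
    if isinstance(axes, int):
        axes = (axes,)
    count = int(np.prod([x.shape[a] for a in axes]))
    return mul(reduce_sum(x, axis, keepdims), _wrap(1.0 / count))


def reduce_max(x: Tensor, axis, keepdims: bool = False) -> Tensor:
    """Max over axes; gradient is split equally among tied maxima."""
    out_data = x.data.max(axis=axis, keepdims=True)
    mask = (x.data == out_data)
    counts = mask.sum(axis=axis, keepdims=True)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis) if isinstance(axis, int) else _reexpand(g, axis)
        _accumulate(x, np.broadcast_to(g / counts, x.shape) * mask)

    data = out_data if keepdims else np.squeeze(out_data, axis=axis)
    return _make(data, (x,), backward)


def _reexpand(g: np.ndarray, axes) -> np.ndarray:
    for a in sorted(axes):
        g = np.expand_dims(g, a)
    return g


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return mul(x, _wrap(mask.astype(x.dtype)))


# ---------------------------------------------------------------------------
# convolution


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)
    return win


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation); x (N,C,H,W), w (O,C,kh,kw)."""
    N, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    win = _im2col(xp, kh, kw, stride)
    N_, C_, Ho, Wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(O, -1)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    out_data = out.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, O)
        _accumulate(w, (gmat.T @ cols).reshape(w.shape))
        if b is not None:
            _accumulate(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            dcols = (gmat @ wmat).reshape(N, Ho, Wo, C, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += (
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            if padding:
                dxp = dxp[:, :, padding : padding + H, padding : padding + W]
            _accumulate(x, dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """Depthwise 2-D convolution; x (N,C,H,W), w (C,kh,kw)."""
    N, C, H, W = x.shape
    Cw, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    win = _im2col(xp, kh, kw, stride)
    Ho, Wo = win.shape[2], win.shape[3]
    out_data = np.einsum("nchwij,cij->nchw", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(g):
        _accumulate(w, np.einsum("nchw,nchwij->cij", g, win, optimize=True))
        if b is not None:
            _accumulate(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += (
                        g * w.data[None, :, i, j, None, None]
                    )
            if padding:
                dxp = dxp[:, :, padding : padding + H, padding : padding + W]
            _accumulate(x, dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


# ---------------------------------------------------------------------------
# batch normalization


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Batch normalization over (N, H, W) per channel, training mode.

    Returns (output, batch_mean, batch_var) — the statistics feed the
    running averages kept by the layer.
    """
    axes = (0, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gma = gamma.data[None, :, None, None]
    out_data = xhat * gma + beta.data[None, :, None, None]

    def backward(g):
        _accumulate(gamma, (g * xhat).sum(axis=axes))
        _accumulate(beta, g.sum(axis=axes))
        if x.requires_grad or x._parents:
            gxh = g * gma
            dx = inv * (
                gxh
                - gxh.mean(axis=axes, keepdims=True)
                - xhat * (gxh * xhat).mean(axis=axes, keepdims=True)
            )
            _accumulate(x, dx)

    out = _make(out_data, (x, gamma, beta), backward)
    return out, mu.squeeze(), var.squeeze()


def batch_norm_eval(x: Tensor, gamma: Tensor, beta: Tensor, running_mean, running_var, eps: float = 1e-5) -> Tensor:
    """Inference-mode batch norm using running statistics (still differentiable
    with respect to x, gamma and beta, as Grad-CAM needs)."""
    inv = (1.0 / np.sqrt(running_var + eps))[None, :, None, None].astype(x.dtype)
    mu = running_mean[None, :, None, None].astype(x.dtype)
    xhat = mul(add(x, _wrap(-mu)), _wrap(inv))
    C = gamma.shape[0]
    return add(mul(xhat, reshape(gamma, (1, C, 1, 1))), reshape(beta, (1, C, 1, 1)))


# ---------------------------------------------------------------------------
# pooling and loss


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C)."""
    return reshape(reduce_mean(x, axis=(2, 3), keepdims=True), (x.shape[0], x.shape[1]))


def global_max_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C)."""
    return reshape(reduce_max(x, axis=(2, 3), keepdims=True), (x.shape[0], x.shape[1]))


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain (non-graph) softmax over the last axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels, fused with softmax."""
    p = softmax(logits.data)
    N = logits.shape[0]
    idx = np.arange(N)
    losses = -np.log(np.clip(p[idx, labels], 1e-12, None))
    out_data = np.array(losses.mean(), dtype=logits.dtype)

    def backward(g):
        d = p.copy()
        d[idx, labels] -= 1.0
        _accumulate(logits, g * d / N)

    return _make(out_data, (logits,), backward)
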