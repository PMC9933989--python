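"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tensor engine sufficient for encoder-decoder convolutional networks:
elementwise arithmetic with broadcasting, matmul, shape ops, reductions,
activations, and a 2-D "same"-padded stride-1 convolution primitive
(im2col forward, col2im backward).  float32 throughout.

Gradients are accumulated by a topological-order sweep from the scalar loss.
Construction of the backward graph is suppressed inside ``no_grad``.
"""

from __future__ import annotations

import numpy as np

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helper -------------------------------------------------

    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # -- properties ----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(out):
            self._accum(_unbroadcast(out.grad, self.data.shape))
            other._accum(_unbroadcast(out.grad, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(out):
            self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(out):
            self._accum(-out.grad)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e

        def backward(out):
            self._accum(out.grad * e * self.data ** (e - 1.0))

        return Tensor._result(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(out):
            self._accum(out.grad @ other.data.T)
            other._accum(self.data.T @ out.grad)

        return Tensor._result(out_data, (self, other), backward)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(out):
            self._accum(out.grad.reshape(old))

        return Tensor._result(out_data, (self,), backward)

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)

        def backward(out):
            self._accum(out.grad.transpose(inv))

        return Tensor._result(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.data.shape

        def backward(out):
            g = np.zeros(shape, dtype=np.float32)
            g[idx] = out.grad
            self._accum(g)

        return Tensor._result(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(out):
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).astype(np.float32))

        return Tensor._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(out):
            expanded = out_data if keepdims else np.expand_dims(out_data, axis)
            mask = (self.data == expanded).astype(np.float32)
            mask /= mask.sum(axis=axis, keepdims=True)  # split ties evenly
            g = out.grad if keepdims else np.expand_dims(out.grad, axis)
            self._accum(mask * g)

        return Tensor._result(out_data, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


# -- activations / elementwise functions --------------------------------------


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0.0)

    def backward(out):
        x._accum(out.grad * (x.data > 0))

    return Tensor._result(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic
    out_data = np.empty_like(x.data)
    pos = x.data >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    out_data[~pos] = ex / (1.0 + ex)

    def backward(out):
        x._accum(out.grad * out_data * (1.0 - out_data))

    return Tensor._result(out_data, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def backward(out):
        x._accum(out.grad * (1.0 - out_data ** 2))

    return Tensor._result(out_data, (x,), backward)


def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)

    def backward(out):
        x._accum(out.grad * out_data)

    return Tensor._result(out_data, (x,), backward)


def log(x: Tensor) -> Tensor:
    def backward(out):
        x._accum(out.grad / x.data)

    return Tensor._result(np.log(x.data), (x,), backward)


def sqrt(x: Tensor) -> Tensor:
    return x ** 0.5


def concat(tensors, axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(out):
        splits = np.cumsum(sizes)[:-1]
        for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
            t._accum(g)

    return Tensor._result(out_data, tuple(tensors), backward)


def pad(x: Tensor, pad_width) -> Tensor:
    """Zero padding; pad_width as for np.pad."""
    out_data = np.pad(x.data, pad_width)
    slices = tuple(
        slice(lo, lo + s) for (lo, _), s in zip(pad_width, x.data.shape)
    )

    def backward(out):
        x._accum(out.grad[slices])

    return Tensor._result(out_data, (x,), backward)


# -- convolution primitive -----------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1 'same' 2-D convolution (cross-correlation).

    x: (N, H, W, Cin); w: (kh, kw, Cin, Cout); b: (Cout,) or None.
    Returns (N, H, W, Cout).
    """
    kh, kw, cin, cout = w.data.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    # (N, H, W, C, kh, kw)
    cols = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    out_data = np.tensordot(cols, w.data, axes=([3, 4, 5], [2, 0, 1]))
    if b is not None:
        out_data = out_data + b.data

    n, h, wd = x.data.shape[0], x.data.shape[1], x.data.shape[2]

    def backward(out):
        dy = out.grad  # (N, H, W, Cout)
        if w.requires_grad:
            dw = np.tensordot(cols, dy, axes=([0, 1, 2], [0, 1, 2]))
            # cols free axes (Cin, kh, kw) -> (kh, kw, Cin, Cout)
            w._accum(dw.transpose(1, 2, 0, 3))
        if b is not None and b.requires_grad:
            b._accum(dy.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            # dcols: (N, H, W, kh, kw, Cin)
            dcols = np.tensordot(dy, w.data, axes=([3], [3]))
            dxp = np.zeros((n, h + 2 * ph, wd + 2 * pw, cin), dtype=np.float32)
            for a in range(kh):
                for c in range(kw):
                    dxp[:, a:a + h, c:c + wd, :] += dcols[:, :, :, a, c, :]
            x._accum(dxp[:, ph:ph + h, pw:pw + wd, :])

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._result(out_data, parents, backward)


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Spatial dims must be even."""
    n, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x2 requires even spatial dims, got {h}x{w}")
    r = x.reshape(n, h // 2, 2, w // 2, 2, c)
    return r.max(axis=4).max(axis=2)


# -- backward sweep ------------------------------------------------------------


def backward(loss: Tensor) -> None:
    """Accumulate gradients of `loss` (a scalar) into all requiring tensors."""
    if loss.data.size != 1:
        raise ValueError("backward() expects a scalar loss")
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in visited:
                stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._backward is not None:
            node._backward(node)
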