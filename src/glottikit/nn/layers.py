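"""Neural-network building blocks on top of the autodiff tensor engine.

Layers follow the NHWC convention: a batch of images is (N, H, W, C) and a
batch of clips is (N, T, H, W, C).  Every layer's ``forward`` takes a
``training`` flag so that batch statistics are handled explicitly.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class with recursive parameter / buffer discovery.

    Traversal follows attribute insertion order, so parameter ordering is
    deterministic for a given architecture — checkpoints are plain lists of
    arrays keyed by position.
    """

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}[{i}]", item

    def parameters(self) -> list[Tensor]:
        params = [
            v for v in vars(self).values()
            if isinstance(v, Tensor) and v.requires_grad
        ]
        for _, child in self._children():
            params.extend(child.parameters())
        return params

    def buffers(self) -> list[np.ndarray]:
        out = list(getattr(self, "_buffers", []))
        for _, child in self._children():
            out.extend(child.buffers())
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()] + [
            b.copy() for b in self.buffers()
        ]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        bufs = self.buffers()
        if len(arrays) != len(params) + len(bufs):
            raise ValueError(
                f"state has {len(arrays)} arrays, model expects "
                f"{len(params) + len(bufs)}"
            )
        for p, a in zip(params, arrays[: len(params)]):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch in checkpoint")
            p.data[...] = a
        for b, a in zip(bufs, arrays[len(params):]):
            b[...] = a

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_normal(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2D(Module):
    """Stride-1 'same' convolution. init='he' for ReLU trunks, 'glorot' for heads."""

    def __init__(self, cin, cout, k=3, bias=True, init="he", rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = k * k * cin
        if init == "he":
            w = _he_normal(rng, (k, k, cin, cout), fan_in)
        else:
            w = _glorot(rng, (k, k, cin, cout), fan_in, k * k * cout)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x, training=False):
        return T.conv2d(x, self.w, self.b)


class ConvTranspose2x2(Module):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling).

    With kernel size equal to stride there is no output overlap, so the op is
    a channel matmul followed by block expansion.
    """

    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Tensor(_glorot(rng, (cin, 2 * 2 * cout), cin, 4 * cout),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True)
        self.cout = cout

    def forward(self, x, training=False):
        n, h, w, cin = x.shape
        y = x.reshape(n * h * w, cin) @ self.w            # (NHW, 4*cout)
        y = y.reshape(n, h, w, 2, 2, self.cout)
        y = y.transpose((0, 1, 3, 2, 4, 5))               # (N, H, 2, W, 2, C)
        return y.reshape(n, 2 * h, 2 * w, self.cout) + self.b


class Dense(Module):
    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Tensor(_glorot(rng, (cin, cout), cin, cout), requires_grad=True)
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True)

    def forward(self, x, training=False):
        return x @ self.w + self.b


class InstanceNorm(Module):
    """Per-sample, per-channel normalization over spatial axes.

    Uses instance statistics in both training and inference (the standard
    convention), so there are no running buffers.
    """

    def __init__(self, c, eps=1e-5):
        self.gamma = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x, training=False):
        axes = tuple(range(1, x.ndim - 1))  # spatial axes
        mu = x.mean(axis=axes, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=axes, keepdims=True)
        xn = xc * (var + self.eps) ** -0.5
        return xn * self.gamma + self.beta


class BatchNorm(Module):
    """Batch normalization over batch+spatial axes with running statistics."""

    def __init__(self, c, eps=1e-5, momentum=0.1):
        self.gamma = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)
        self._buffers = [self.running_mean, self.running_var]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean *= 1 - m
            self.running_mean += m * mu.data.reshape(-1)
            self.running_var *= 1 - m
            self.running_var += m * var.data.reshape(-1)
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
            xc = x - mu
        xn = xc * (var + self.eps) ** -0.5
        return xn * self.gamma + self.beta


def make_norm(kind: str, c: int) -> Module:
    if kind == "instance":
        return InstanceNorm(c)
    if kind == "batch":
        return BatchNorm(c)
    raise ValueError(f"unknown normalization '{kind}' (use 'batch' or 'instance')")


class Conv3D(Module):
    """Stride-1 'same' 3-D convolution over (N, T, H, W, C) clips.

    Implemented as a sum over temporal kernel offsets of 2-D convolutions with
    time folded into the batch axis, which keeps peak memory proportional to a
    single 2-D im2col buffer.
    """

    def __init__(self, cin, cout, k=3, kt=3, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = kt * k * k * cin
        self.ws = [
            Tensor(_he_normal(rng, (k, k, cin, cout), fan_in), requires_grad=True)
            for _ in range(kt)
        ]
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True)
        self.kt = kt

    def parameters(self):
        return list(self.ws) + [self.b]

    def forward(self, x, training=False):
        n, t, h, w, cin = x.shape
        pt = self.kt // 2
        xp = T.pad(x, ((0, 0), (pt, pt), (0, 0), (0, 0), (0, 0)))
        out = None
        for d in range(self.kt):
            sl = xp[:, d:d + t]
            folded = sl.reshape(n * t, h, w, cin)
            y = T.conv2d(folded, self.ws[d])
            out = y if out is None else out + y
        cout = self.ws[0].shape[3]
        return out.reshape(n, t, h, w, cout) + self.b


class ConvLSTM2D(Module):
    """Convolutional LSTM over an image sequence (N, T, H, W, C) -> (N, T, H, W, Cout).

    Gates are computed with 'same' 3x3 convolutions on the input and the hidden
    state; the cell state carries spatial feature maps across frames.
    """

    def __init__(self, cin, cout, k=3, rng=None):
        rng = rng or np.random.default_rng(0)
        self.wx = Conv2D(cin, 4 * cout, k=k, bias=True, init="glorot", rng=rng)
        self.wh = Conv2D(cout, 4 * cout, k=k, bias=False, init="glorot", rng=rng)
        self.cout = cout
        # forget-gate bias init to 1 for stable early memory
        self.wx.b.data[cout:2 * cout] = 1.0

    def forward(self, x, training=False):
        n, t, h, w, _ = x.shape
        c = self.cout
        h_t = Tensor(np.zeros((n, h, w, c), np.float32))
        c_t = Tensor(np.zeros((n, h, w, c), np.float32))
        outs = []
        for step in range(t):
            frame = x[:, step]
            gates = self.wx(frame) + self.wh(h_t)
            i = T.sigmoid(gates[:, :, :, 0:c])
            f = T.sigmoid(gates[:, :, :, c:2 * c])
            g = T.tanh(gates[:, :, :, 2 * c:3 * c])
            o = T.sigmoid(gates[:, :, :, 3 * c:4 * c])
            c_t = f * c_t + i * g
            h_t = o * T.tanh(c_t)
            outs.append(h_t.reshape(n, 1, h, w, c))
        return T.concat(outs, axis=1)
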