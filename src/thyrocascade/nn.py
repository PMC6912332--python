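"""Compact NumPy neural-network layers with manual backprop.

Just enough machinery for the classifier stage: 2-D convolution (im2col),
batch normalization (2-D and 1-D), ReLU, max/global-average pooling,
dropout, dense layers, residual blocks, a softmax cross-entropy loss and an
Adam optimizer. Tensors are NCHW float32. Every layer exposes its
parameters as :class:`Param` objects so the whole network can be counted,
flattened, serialized and updated generically.

This is a deliberately small static framework: layers are composed in
:class:`Sequential` / :class:`Residual` containers, and backward passes
mirror the forward call order. It is sized for the small backbones used in
this package, not for general deep-learning workloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Param", "Layer", "Sequential", "Residual",
    "Conv2D", "BatchNorm2D", "BatchNorm1D", "ReLU",
    "MaxPool2D", "GlobalAvgPool2D", "Dropout", "Dense",
    "softmax", "softmax_cross_entropy", "Adam",
]


@dataclass
class Param:
    """One parameter tensor with its gradient and trainability flag.

    Batch-norm running statistics are non-trainable parameters: they are
    carried (and counted, when asked) but never touched by the optimizer.
    """

    name: str
    value: np.ndarray
    trainable: bool = True
    grad: np.ndarray | None = field(default=None, repr=False)

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base layer: forward/backward plus recursive parameter listing."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training=training)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Identity(Layer):
    def forward(self, x, training=False):
        return x

    def backward(self, grad):
        return grad


class Residual(Layer):
    """y = relu(main(x) + shortcut(x)); shortcut defaults to identity."""

    def __init__(self, main: Layer, shortcut: Layer | None = None):
        self.main = main
        self.shortcut = shortcut or Identity()

    def params(self) -> list[Param]:
        return self.main.params() + self.shortcut.params()

    def forward(self, x, training=False):
        s = self.main.forward(x, training=training) + \
            self.shortcut.forward(x, training=training)
        self._mask = s > 0
        return s * self._mask

    def backward(self, grad):
        grad = grad * self._mask
        return self.main.backward(grad) + self.shortcut.backward(grad)


def _pad(x, p):
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


class Conv2D(Layer):
    """k x k convolution with optional bias, He-initialized.

    Forward uses an im2col view (sliding_window_view + matmul); backward
    accumulates the input gradient with a k^2 loop of strided adds, which
    is fully vectorized over batch and space.
    """

    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * kernel * kernel))
        w = rng.normal(0.0, scale, size=(cout, cin, kernel, kernel))
        self.w = Param(f"{name}.w", w.astype(np.float32))
        self.b = Param(f"{name}.b", np.zeros(cout, np.float32)) if bias else None
        self.stride, self.pad, self.kernel = stride, pad, kernel
        self.cin, self.cout = cin, cout

    def params(self):
        return [self.w] + ([self.b] if self.b else [])

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        xp = _pad(x, p)
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]                       # (n, c, oh, ow, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        wmat = self.w.value.reshape(self.cout, -1)      # (cout, c*k*k)
        out = cols @ wmat.T
        if self.b:
            out += self.b.value
        self._cache = (cols, x.shape, oh, ow)
        return out.reshape(n, oh, ow, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, xshape, oh, ow = self._cache
        n, c, h, w = xshape
        k, s, p = self.kernel, self.stride, self.pad
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.cout)  # (n*oh*ow, cout)
        self.w.grad = (g.T @ cols).reshape(self.w.value.shape)
        if self.b:
            self.b.grad = g.sum(axis=0)
        dcols = (g @ self.w.value.reshape(self.cout, -1))
        dcols = dcols.reshape(n, oh, ow, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class _BatchNormBase(Layer):
    def __init__(self, k: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(f"{name}.gamma", np.ones(k, np.float32))
        self.beta = Param(f"{name}.beta", np.zeros(k, np.float32))
        self.running_mean = Param(f"{name}.running_mean",
                                  np.zeros(k, np.float32), trainable=False)
        self.running_var = Param(f"{name}.running_var",
                                 np.ones(k, np.float32), trainable=False)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    _axes: tuple  # reduction axes; set by subclasses

    def _shape(self, k):  # broadcast shape for per-feature vectors
        raise NotImplementedError

    def forward(self, x, training=False):
        k = self.gamma.value.shape[0]
        sh = self._shape(k)
        if training:
            mean = x.mean(axis=self._axes)
            var = x.var(axis=self._axes)
            m = self.momentum
            self.running_mean.value = (m * self.running_mean.value
                                       + (1 - m) * mean).astype(np.float32)
            self.running_var.value = (m * self.running_var.value
                                      + (1 - m) * var).astype(np.float32)
        else:
            mean, var = self.running_mean.value, self.running_var.value
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
        self._cache = (xhat, inv.reshape(sh))
        return self.gamma.value.reshape(sh) * xhat + self.beta.value.reshape(sh)

    def backward(self, grad):
        xhat, inv = self._cache
        sh = inv.shape
        axes = self._axes
        m = np.prod([grad.shape[a] for a in axes])
        self.gamma.grad = (grad * xhat).sum(axis=axes)
        self.beta.grad = grad.sum(axis=axes)
        g = grad * self.gamma.value.reshape(sh)
        return (inv / m) * (m * g
                            - g.sum(axis=axes, keepdims=True)
                            - xhat * (g * xhat).sum(axis=axes, keepdims=True))


class BatchNorm2D(_BatchNormBase):
    """Per-channel normalization of NCHW tensors."""

    _axes = (0, 2, 3)

    def _shape(self, k):
        return (1, k, 1, 1)


class BatchNorm1D(_BatchNormBase):
    """Per-feature normalization of (N, k) tensors (the classifier head)."""

    _axes = (0,)

    def _shape(self, k):
        return (1, k)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2D(Layer):
    def __init__(self, kernel: int = 2, stride: int | None = None, pad: int = 0):
        self.kernel = kernel
        self.stride = stride or kernel
        self.pad = pad

    def forward(self, x, training=False):
        k, s, p = self.kernel, self.stride, self.pad
        xp = _pad(x, p) if p else x
        if p:
            xp = xp.copy()
            xp[:, :, :p, :] = -np.inf
            xp[:, :, -p:, :] = -np.inf
            xp[:, :, :, :p] = -np.inf
            xp[:, :, :, -p:] = -np.inf
        n, c, h, w = xp.shape
        oh = (h - k) // s + 1
        ow = (w - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s].reshape(n, c, oh, ow, k * k)
        self._argmax = win.argmax(axis=-1)
        self._xshape, self._padded = x.shape, (h, w)
        return win.max(axis=-1)

    def backward(self, grad):
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = self._xshape
        ph, pw = self._padded
        n_, c_, oh, ow = grad.shape
        dxp = np.zeros((n, c, ph, pw), dtype=grad.dtype)
        ii, jj = np.divmod(self._argmax, k)
        oi, oj = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
        ri = oi[None, None] * s + ii
        cj = oj[None, None] * s + jj
        bn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (bn, cc, ri, cj), grad)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class GlobalAvgPool2D(Layer):
    """(N, C, H, W) -> (N, C) spatial mean; the head's pooling step."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Dropout(Layer):
    """Inverted dropout; inactive outside training."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Dense(Layer):
    def __init__(self, nin: int, nout: int,
                 rng: np.random.Generator | None = None, name: str = "dense"):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / nin)
        self.w = Param(f"{name}.w",
                       rng.normal(0, scale, (nin, nout)).astype(np.float32))
        self.b = Param(f"{name}.b", np.zeros(nout, np.float32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad = self._x.T @ grad
        self.b.grad = grad.sum(axis=0)
        return grad @ self.w.value.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


class Adam:
    """Adaptive-moment gradient descent over a network's trainable params."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value = (p.value - self.lr * mhat /
                       (np.sqrt(vhat) + self.eps)).astype(np.float32)
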