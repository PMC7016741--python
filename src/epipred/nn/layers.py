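"""Minimal 1-D neural-network layers with explicit backpropagation.

Array layout follows the channels-last convention: activations are
(batch, length, channels) for convolutional stages and (batch, features)
after flattening. Each layer owns its parameters, gradients and (for batch
normalization) running statistics, and implements ``forward``/``backward``.

Parameters are tracked as :class:`Param` records; ``kind`` distinguishes
convolution kernels (which receive L2 weight decay during training) from
everything else, and ``trainable`` separates weights from batch-norm
running statistics so that both parameter-accounting conventions (total
vs. trainable-only) can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np


@dataclass
class Param:
    name: str
    value: np.ndarray
    kind: str = "weight"        # "conv_kernel", "weight", "bias", "bn", "bn_stat"
    trainable: bool = True
    grad: Optional[np.ndarray] = None


class Layer:
    """Base class. Subclasses fill ``self.params`` at build time."""

    def __init__(self):
        self.params: List[Param] = []
        self.built = False

    # -- parameter bookkeeping -------------------------------------------
    def add_param(self, name, value, kind="weight", trainable=True) -> Param:
        p = Param(name, np.asarray(value, dtype=np.float64), kind, trainable)
        self.params.append(p)
        return p

    def all_params(self) -> List[Param]:
        return self.params

    # -- interface --------------------------------------------------------
    def build(self, input_shape, rng):
        self.built = True
        return self.output_shape(input_shape)

    def output_shape(self, input_shape):
        return input_shape

    def forward(self, x, training=False, rng=None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


def glorot_uniform_bounds(fan_in: int, fan_out: int):
    """Symmetric bounds +-sqrt(6/(fan_in+fan_out)) of the Glorot uniform
    initializer."""
    if fan_in < 1 or fan_out < 1:
        raise ValueError("fan_in and fan_out must be positive")
    b = np.sqrt(6.0 / (fan_in + fan_out))
    return (-b, b)


def _init_kernel(shape, fan_in, fan_out, scheme, rng):
    if scheme == "glorot_uniform":
        lo, hi = glorot_uniform_bounds(fan_in, fan_out)
        return rng.uniform(lo, hi, size=shape)
    if scheme == "he_normal":
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    raise ValueError(f"unknown init scheme {scheme!r}")


class Dense(Layer):
    def __init__(self, units: int, use_bias: bool = True, init: str = "glorot_uniform"):
        super().__init__()
        if units < 1:
            raise ValueError("units must be positive")
        self.units = units
        self.use_bias = use_bias
        self.init = init

    def build(self, input_shape, rng):
        (n_in,) = input_shape
        self.w = self.add_param(
            "kernel", _init_kernel((n_in, self.units), n_in, self.units, self.init, rng))
        if self.use_bias:
            self.b = self.add_param("bias", np.zeros(self.units), kind="bias")
        self.built = True
        return (self.units,)

    def output_shape(self, input_shape):
        return (self.units,)

    def forward(self, x, training=False, rng=None):
        self._x = x
        y = x @ self.w.value
        if self.use_bias:
            y = y + self.b.value
        return y

    def backward(self, dy):
        self.w.grad = self._x.T @ dy
        if self.use_bias:
            self.b.grad = dy.sum(axis=0)
        return dy @ self.w.value.T


class Conv1D(Layer):
    """1-D convolution over (batch, length, channels) input."""

    def __init__(self, filters: int, kernel_size: int, stride: int = 1,
                 padding: str = "valid", use_bias: bool = True,
                 init: str = "glorot_uniform"):
        super().__init__()
        if filters < 1 or kernel_size < 1 or stride < 1:
            raise ValueError("filters, kernel_size and stride must be positive")
        if padding not in ("valid", "same"):
            raise ValueError("padding must be 'valid' or 'same'")
        self.filters = filters
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.use_bias = use_bias
        self.init = init

    def _out_len(self, L):
        if self.padding == "same":
            return -(-L // self.stride)
        if L < self.kernel_size:
            raise ValueError(f"input length {L} shorter than kernel {self.kernel_size}")
        return (L - self.kernel_size) // self.stride + 1

    def build(self, input_shape, rng):
        L, cin = input_shape
        self.cin = cin
        k = self.kernel_size
        fan_in, fan_out = k * cin, k * self.filters
        self.w = self.add_param(
            "kernel", _init_kernel((k, cin, self.filters), fan_in, fan_out, self.init, rng),
            kind="conv_kernel")
        if self.use_bias:
            self.b = self.add_param("bias", np.zeros(self.filters), kind="bias")
        self.built = True
        return (self._out_len(L), self.filters)

    def output_shape(self, input_shape):
        return (self._out_len(input_shape[0]), self.filters)

    def _pad_amounts(self, L):
        out = -(-L // self.stride)
        total = max((out - 1) * self.stride + self.kernel_size - L, 0)
        return total // 2, total - total // 2

    def forward(self, x, training=False, rng=None):
        if self.padding == "same":
            lo, hi = self._pad_amounts(x.shape[1])
            xp = np.pad(x, ((0, 0), (lo, hi), (0, 0)))
            self._pad = (lo, hi)
        else:
            xp = x
            self._pad = (0, 0)
        B, Lp, C = xp.shape
        k, s = self.kernel_size, self.stride
        W = (Lp - k) // s + 1
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B, Lp-k+1, C, k)
        cols = cols[:, ::s]                                             # (B, W, C, k)
        self._cols = cols
        self._in_len = x.shape[1]
        y = np.einsum("bwck,kcf->bwf", cols, self.w.value, optimize=True)
        if self.use_bias:
            y = y + self.b.value
        return y

    def backward(self, dy):
        # dW
        self.w.grad = np.einsum("bwck,bwf->kcf", self._cols, dy, optimize=True)
        if self.use_bias:
            self.b.grad = dy.sum(axis=(0, 1))
        # dX: scatter each kernel tap back onto the padded input grid
        B, W, _ = dy.shape
        k, s = self.kernel_size, self.stride
        lo, hi = self._pad
        Lp = self._in_len + lo + hi
        dxp = np.zeros((B, Lp, self.cin))
        # contribution of tap t: dxp[:, w*s + t, :] += dy[:, w, :] @ w[t].T
        g = np.einsum("bwf,kcf->bwkc", dy, self.w.value, optimize=True)
        idx = (np.arange(W)[:, None] * s + np.arange(k)[None, :]).ravel()
        np.add.at(dxp, (slice(None), idx), g.reshape(B, W * k, self.cin))
        return dxp[:, lo:Lp - hi if hi else Lp, :]


class _Pool1D(Layer):
    def __init__(self, pool_size: int, stride: Optional[int] = None,
                 padding: str = "valid"):
        super().__init__()
        if pool_size < 1:
            raise ValueError("pool_size must be positive")
        self.pool_size = pool_size
        self.stride = stride or pool_size
        self.padding = padding

    def _out_len(self, L):
        if self.padding == "same":
            return -(-L // self.stride)
        return (L - self.pool_size) // self.stride + 1

    def output_shape(self, input_shape):
        return (self._out_len(input_shape[0]), input_shape[1])

    def _windows(self, x):
        if self.padding == "same":
            out = -(-x.shape[1] // self.stride)
            need = (out - 1) * self.stride + self.pool_size - x.shape[1]
            if need > 0:
                fill = -np.inf if isinstance(self, MaxPool1D) else 0.0
                x = np.pad(x, ((0, 0), (0, need), (0, 0)), constant_values=fill)
        v = np.lib.stride_tricks.sliding_window_view(x, self.pool_size, axis=1)
        return x, v[:, ::self.stride]            # (B, W, C, pool)


class MaxPool1D(_Pool1D):
    def forward(self, x, training=False, rng=None):
        self._in_shape = x.shape
        xp, win = self._windows(x)
        self._arg = win.argmax(axis=-1)          # (B, W, C)
        self._padded_len = xp.shape[1]
        return win.max(axis=-1)

    def backward(self, dy):
        B, W, C = dy.shape
        dx = np.zeros((B, self._padded_len, C))
        b, w, c = np.ix_(np.arange(B), np.arange(W), np.arange(C))
        pos = w * self.stride + self._arg
        np.add.at(dx, (b, pos, c), dy)
        return dx[:, :self._in_shape[1], :]


class AvgPool1D(_Pool1D):
    def forward(self, x, training=False, rng=None):
        self._in_shape = x.shape
        xp, win = self._windows(x)
        self._padded_len = xp.shape[1]
        return win.mean(axis=-1)

    def backward(self, dy):
        B, W, C = dy.shape
        dx = np.zeros((B, self._padded_len, C))
        idx = (np.arange(W)[:, None] * self.stride + np.arange(self.pool_size)[None, :]).ravel()
        g = np.repeat(dy[:, :, None, :] / self.pool_size, self.pool_size, axis=2)
        np.add.at(dx, (slice(None), idx), g.reshape(B, W * self.pool_size, C))
        return dx[:, :self._in_shape[1], :]


class GlobalAvgPool1D(Layer):
    """Mean over the length axis: (B, L, C) -> (B, C)."""

    def output_shape(self, input_shape):
        return (input_shape[1],)

    def forward(self, x, training=False, rng=None):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :] / self._L, self._L, axis=1)


class ChannelMean(Layer):
    """Mean over the channel axis: (B, L, C) -> (B, L).

    Used by the sequence ResNet head, whose final feature is the per-position
    average of the channel maps rather than a per-channel pooled vector.
    """

    def output_shape(self, input_shape):
        return (input_shape[0],)

    def forward(self, x, training=False, rng=None):
        self._C = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None] / self._C, self._C, axis=2)


class Flatten(Layer):
    def output_shape(self, input_shape):
        n = 1
        for d in input_shape:
            n *= d
        return (n,)

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class BatchNorm(Layer):
    """Batch normalization over the channel (last) axis.

    gamma/beta are trainable; running mean/var are non-trainable statistics
    counted only in the 'total' parameter convention.
    """

    def __init__(self, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.momentum = momentum
        self.eps = eps

    def build(self, input_shape, rng):
        c = input_shape[-1]
        self.gamma = self.add_param("gamma", np.ones(c), kind="bn")
        self.beta = self.add_param("beta", np.zeros(c), kind="bn")
        self.r_mean = self.add_param("moving_mean", np.zeros(c), kind="bn_stat",
                                     trainable=False)
        self.r_var = self.add_param("moving_var", np.ones(c), kind="bn_stat",
                                    trainable=False)
        self.built = True
        return input_shape

    def forward(self, x, training=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.r_mean.value = m * self.r_mean.value + (1 - m) * mean
            self.r_var.value = m * self.r_var.value + (1 - m) * var
        else:
            mean, var = self.r_mean.value, self.r_var.value
        self._axes = axes
        self._n = x.size // x.shape[-1]
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy):
        axes = self._axes
        self.gamma.grad = (dy * self._xhat).sum(axis=axes)
        self.beta.grad = dy.sum(axis=axes)
        if not self._training:
            return dy * self.gamma.value / self._std
        n = self._n
        dxhat = dy * self.gamma.value
        return (dxhat - dxhat.mean(axis=axes)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        super().__init__()
        self.layers = list(layers)

    def build(self, input_shape, rng):
        shape = input_shape
        for lyr in self.layers:
            shape = lyr.build(shape, rng) if not lyr.built else lyr.output_shape(shape)
        self.built = True
        return shape

    def output_shape(self, input_shape):
        shape = input_shape
        for lyr in self.layers:
            shape = lyr.output_shape(shape)
        return shape

    def all_params(self):
        out = []
        for lyr in self.layers:
            out.extend(lyr.all_params())
        return out

    def forward(self, x, training=False, rng=None):
        for lyr in self.layers:
            x = lyr.forward(x, training=training, rng=rng)
        return x

    def backward(self, dy):
        for lyr in reversed(self.layers):
            dy = lyr.backward(dy)
        return dy


class AttentionGate(Layer):
    """Multiplicative dense attention: y = x * sigmoid(BN?(W x)).

    Realizes an "N-d attention, multiply the outputs" head stage as a dense
    layer of the same width with logistic activation whose output gates the
    incoming activation elementwise.
    """

    def __init__(self, units: int, use_bias: bool = False, batchnorm: bool = True):
        super().__init__()
        self.dense = Dense(units, use_bias=use_bias)
        self.bn = BatchNorm() if batchnorm else None

    def build(self, input_shape, rng):
        shape = self.dense.build(input_shape, rng)
        if self.bn is not None:
            self.bn.build(shape, rng)
        self.built = True
        return input_shape

    def all_params(self):
        out = list(self.dense.all_params())
        if self.bn is not None:
            out.extend(self.bn.all_params())
        return out

    def forward(self, x, training=False, rng=None):
        z = self.dense.forward(x, training=training)
        if self.bn is not None:
            z = self.bn.forward(z, training=training)
        self._a = 1.0 / (1.0 + np.exp(-z))
        self._x = x
        return x * self._a

    def backward(self, dy):
        da = dy * self._x * self._a * (1.0 - self._a)
        if self.bn is not None:
            da = self.bn.backward(da)
        dx_gate = self.dense.backward(da)
        return dy * self._a + dx_gate


class ZeroPadShortcut(Layer):
    """Parameter-free residual shortcut: strided slice plus channel
    zero-padding (option-A shortcut of deep residual networks)."""

    def __init__(self, out_channels: int, stride: int = 1):
        super().__init__()
        self.out_channels = out_channels
        self.stride = stride

    def output_shape(self, input_shape):
        L, C = input_shape
        return (-(-L // self.stride), self.out_channels)

    def forward(self, x, training=False, rng=None):
        self._in_channels = x.shape[2]
        y = x[:, ::self.stride, :]
        extra = self.out_channels - self._in_channels
        if extra > 0:
            y = np.pad(y, ((0, 0), (0, 0), (0, extra)))
        self._in_len = x.shape[1]
        return y

    def backward(self, dy):
        dy = dy[:, :, :self._in_channels]
        B, W, C = dy.shape
        dx = np.zeros((B, self._in_len, C))
        dx[:, ::self.stride, :] = dy
        return dx


class ResidualBlock(Layer):
    """Two same-padded convolutions with batch norm and a skip connection.

    ``shortcut`` is one of 'identity', 'zeropad', or 'projection'
    (1x1 convolution, optionally batch-normalized).
    """

    def __init__(self, filters: int, kernel_size: int, stride: int = 1,
                 shortcut: str = "identity", projection_bn: bool = True,
                 init: str = "he_normal"):
        super().__init__()
        self.conv1 = Conv1D(filters, kernel_size, stride=stride, padding="same",
                            use_bias=False, init=init)
        self.bn1 = BatchNorm()
        self.conv2 = Conv1D(filters, kernel_size, stride=1, padding="same",
                            use_bias=False, init=init)
        self.bn2 = BatchNorm()
        self.relu1 = ReLU()
        self.relu_out = ReLU()
        self.shortcut_kind = shortcut
        if shortcut == "projection":
            self.proj = Conv1D(filters, 1, stride=stride, padding="same",
                               use_bias=False, init=init)
            self.proj_bn = BatchNorm() if projection_bn else None
        elif shortcut == "zeropad":
            self.proj = ZeroPadShortcut(filters, stride=stride)
            self.proj_bn = None
        else:
            self.proj = None
            self.proj_bn = None
            if stride != 1:
                raise ValueError("identity shortcut requires stride 1")

    def build(self, input_shape, rng):
        s = self.conv1.build(input_shape, rng)
        self.bn1.build(s, rng)
        s2 = self.conv2.build(s, rng)
        self.bn2.build(s2, rng)
        if self.proj is not None:
            ps = self.proj.build(input_shape, rng) if isinstance(self.proj, Conv1D) \
                else self.proj.output_shape(input_shape)
            if self.proj_bn is not None:
                self.proj_bn.build(ps, rng)
        self.built = True
        return s2

    def output_shape(self, input_shape):
        return self.conv2.output_shape(self.conv1.output_shape(input_shape))

    def all_params(self):
        out = (self.conv1.all_params() + self.bn1.all_params()
               + self.conv2.all_params() + self.bn2.all_params())
        if isinstance(self.proj, Conv1D):
            out.extend(self.proj.all_params())
        if self.proj_bn is not None:
            out.extend(self.proj_bn.all_params())
        return out

    def forward(self, x, training=False, rng=None):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training),
                                                training), training)
        h = self.bn2.forward(self.conv2.forward(h, training), training)
        if self.proj is not None:
            s = self.proj.forward(x, training)
            if self.proj_bn is not None:
                s = self.proj_bn.forward(s, training)
        else:
            s = x
        return self.relu_out.forward(h + s, training)

    def backward(self, dy):
        dy = self.relu_out.backward(dy)
        dh, ds = dy, dy
        dh = self.conv2.backward(self.bn2.backward(dh))
        dh = self.conv1.backward(self.bn1.backward(self.relu1.backward(dh)))
        if self.proj is not None:
            if self.proj_bn is not None:
                ds = self.proj_bn.backward(ds)
            ds = self.proj.backward(ds)
        return dh + ds
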