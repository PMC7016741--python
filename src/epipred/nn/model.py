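"""Branched network container, output heads and the Adam optimizer."""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .layers import Dense, Layer, Param, Sequential


class SigmoidOutput(Layer):
    """Dense(1) + logistic output. Gradient is computed jointly with the
    (weighted) binary cross-entropy for numerical stability."""

    n_classes = 1

    def __init__(self, use_bias: bool = True):
        super().__init__()
        self.dense = Dense(1, use_bias=use_bias)

    def build(self, input_shape, rng):
        self.dense.build(input_shape, rng)
        self.built = True
        return (1,)

    def output_shape(self, input_shape):
        return (1,)

    def all_params(self):
        return self.dense.all_params()

    def forward(self, x, training=False, rng=None):
        z = self.dense.forward(x, training=training)[:, 0]
        self._p = 1.0 / (1.0 + np.exp(-z))
        return self._p

    def proba(self):
        return self._p

    def backward_from_logit_grad(self, dz):
        return self.dense.backward(dz[:, None])

    def backward(self, dy):          # generic path (dL/dp)
        dz = dy * self._p * (1.0 - self._p)
        return self.dense.backward(dz[:, None])


class SoftmaxOutput(Layer):
    """Dense(2) + softmax; probability of the positive class is column 1.

    Used where the resolved architecture ends in a two-unit output layer.
    """

    n_classes = 2

    def __init__(self, use_bias: bool = True):
        super().__init__()
        self.dense = Dense(2, use_bias=use_bias)

    def build(self, input_shape, rng):
        self.dense.build(input_shape, rng)
        self.built = True
        return (2,)

    def output_shape(self, input_shape):
        return (2,)

    def all_params(self):
        return self.dense.all_params()

    def forward(self, x, training=False, rng=None):
        z = self.dense.forward(x, training=training)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._sm = e / e.sum(axis=1, keepdims=True)
        return self._sm[:, 1]

    def proba(self):
        return self._sm[:, 1]

    def backward_from_logit_grad(self, dz_pos):
        # dz_pos is dL/dz1 under the two-class softmax parameterization
        dz = np.stack([-dz_pos, dz_pos], axis=1)
        return self.dense.backward(dz)


class BranchedModel:
    """A two-branch (or single-trunk) network with a merge point and a head.

    ``merge`` controls how the enhancer and promoter inputs combine:

    - ``"flatten_concat"``: each branch runs separately, outputs are
      flattened and concatenated feature-wise before the head;
    - ``"length_concat"``: inputs are concatenated along the length axis
      first and a single trunk (the enhancer branch) processes the result;
    - ``"branch_length_concat"``: each branch runs separately and the 3-D
      branch outputs (equal channel width) are concatenated along the
      length axis; the head then starts from a (batch, length, channels)
      tensor (e.g. a global pooling stage).
    """

    def __init__(self, name: str,
                 enhancer_branch: Sequential,
                 promoter_branch: Optional[Sequential],
                 head: Sequential,
                 output: Layer,
                 input_shapes: Tuple[Tuple[int, int], Tuple[int, int]],
                 merge: str = "flatten_concat",
                 metadata: Optional[Dict] = None):
        self.name = name
        self.enh = enhancer_branch
        self.prom = promoter_branch
        self.head = head
        self.output = output
        self.input_shapes = input_shapes
        self.merge = merge
        self.metadata = metadata or {}
        self.frozen: bool = False
        self._built = False

    # -- construction -----------------------------------------------------
    def build(self, rng) -> "BranchedModel":
        se, sp = self.input_shapes
        if self.merge == "length_concat":
            trunk_in = (se[0] + sp[0], se[1])
            shape = self.enh.build(trunk_in, rng)
            if len(shape) > 1:
                shape = (int(np.prod(shape)),)
            self._flat = None
        elif self.merge == "flatten_concat":
            oe = self.enh.build(se, rng)
            op = self.prom.build(sp, rng) if self.prom is not None else None
            ne = int(np.prod(oe))
            npb = int(np.prod(op)) if op is not None else 0
            shape = (ne + npb,)
            self._branch_shapes = (oe, op)
        elif self.merge == "branch_length_concat":
            oe = self.enh.build(se, rng)
            op = self.prom.build(sp, rng)
            if oe[1] != op[1]:
                raise ValueError("branch channel widths differ: "
                                 f"{oe[1]} vs {op[1]}")
            shape = (oe[0] + op[0], oe[1])
            self._branch_shapes = (oe, op)
        else:
            raise ValueError(f"unknown merge mode {self.merge!r}")
        shape = self.head.build(shape, rng)
        self.output.build(shape, rng)
        self._built = True
        return self

    # -- parameters -------------------------------------------------------
    def all_params(self) -> List[Param]:
        out = list(self.enh.all_params())
        if self.prom is not None:
            out.extend(self.prom.all_params())
        out.extend(self.head.all_params())
        out.extend(self.output.all_params())
        return out

    def trainable_params(self) -> List[Param]:
        if self.frozen:
            return [p for p in self.head.all_params() + self.output.all_params()
                    if p.trainable]
        return [p for p in self.all_params() if p.trainable]

    def snapshot(self) -> List[np.ndarray]:
        return [p.value.copy() for p in self.all_params()]

    def restore(self, snap: Sequence[np.ndarray]):
        for p, v in zip(self.all_params(), snap):
            p.value = v.copy()

    # -- execution --------------------------------------------------------
    def forward(self, xe: np.ndarray, xp: np.ndarray, training: bool = False,
                rng=None) -> np.ndarray:
        se, sp = self.input_shapes
        if tuple(xe.shape[1:]) != tuple(se) or tuple(xp.shape[1:]) != tuple(sp):
            raise ValueError(
                f"{self.name} expects inputs {se} and {sp}; got "
                f"{tuple(xe.shape[1:])} and {tuple(xp.shape[1:])}")
        if self.merge == "length_concat":
            x = np.concatenate([xe, xp], axis=1)
            h = self.enh.forward(x, training=training, rng=rng)
            if h.ndim == 3:
                h = h.reshape(h.shape[0], -1)
            self._merge_info = None
        elif self.merge == "branch_length_concat":
            he = self.enh.forward(xe, training=training, rng=rng)
            hp = self.prom.forward(xp, training=training, rng=rng)
            h = np.concatenate([he, hp], axis=1)
            self._merge_info = (he.shape, hp.shape, he.shape[1])
        else:
            he = self.enh.forward(xe, training=training, rng=rng)
            he_flat = he.reshape(he.shape[0], -1)
            if self.prom is not None:
                hp = self.prom.forward(xp, training=training, rng=rng)
                hp_flat = hp.reshape(hp.shape[0], -1)
                h = np.concatenate([he_flat, hp_flat], axis=1)
                self._merge_info = (he.shape, hp.shape, he_flat.shape[1])
            else:
                h = he_flat
                self._merge_info = (he.shape, None, he_flat.shape[1])
        h = self.head.forward(h, training=training, rng=rng)
        self._head_out = h
        return self.output.forward(h, training=training, rng=rng)

    def predict_proba(self, xe, xp, batch_size: int = 512) -> np.ndarray:
        out = []
        for i in range(0, xe.shape[0], batch_size):
            out.append(self.forward(xe[i:i + batch_size], xp[i:i + batch_size],
                                    training=False))
        return np.concatenate(out)

    def backward_from_logit_grad(self, dz):
        dh = self.output.backward_from_logit_grad(dz)
        dh = self.head.backward(dh)
        if self.frozen:
            return
        if self.merge == "length_concat":
            if dh.ndim == 2:
                # trunk output was 3-D and flattened implicitly
                out_shape = self.enh.output_shape(
                    (self.input_shapes[0][0] + self.input_shapes[1][0],
                     self.input_shapes[0][1]))
                if len(out_shape) == 2:
                    dh = dh.reshape(dh.shape[0], *out_shape)
            self.enh.backward(dh)
        elif self.merge == "branch_length_concat":
            he_shape, hp_shape, le = self._merge_info
            self.enh.backward(dh[:, :le, :])
            self.prom.backward(dh[:, le:, :])
        else:
            he_shape, hp_shape, ne = self._merge_info
            de = dh[:, :ne].reshape(he_shape)
            self.enh.backward(de)
            if self.prom is not None:
                dp = dh[:, ne:].reshape(hp_shape)
                self.prom.backward(dp)

    def penultimate_features(self, xe, xp, batch_size: int = 512) -> np.ndarray:
        """Activations entering the output layer (the high-level features
        used by the combined model)."""
        out = []
        for i in range(0, xe.shape[0], batch_size):
            self.forward(xe[i:i + batch_size], xp[i:i + batch_size], training=False)
            out.append(self._head_out.copy())
        return np.concatenate(out)


class VectorModel:
    """A plain feed-forward network over flat feature vectors (the FNN and
    the combined-model head). Mirrors the :class:`BranchedModel` interface
    with a single input array."""

    def __init__(self, name: str, body: Sequential, output: Layer,
                 input_dim: int, metadata: Optional[Dict] = None):
        if input_dim < 1:
            raise ValueError("input_dim must be positive")
        self.name = name
        self.body = body
        self.output = output
        self.input_dim = input_dim
        self.metadata = metadata or {}
        self.frozen = False

    def build(self, rng) -> "VectorModel":
        shape = self.body.build((self.input_dim,), rng)
        self.output.build(shape, rng)
        return self

    def all_params(self) -> List[Param]:
        return self.body.all_params() + self.output.all_params()

    def trainable_params(self) -> List[Param]:
        return [p for p in self.all_params() if p.trainable]

    def snapshot(self):
        return [p.value.copy() for p in self.all_params()]

    def restore(self, snap):
        for p, v in zip(self.all_params(), snap):
            p.value = v.copy()

    def forward(self, x, training: bool = False, rng=None) -> np.ndarray:
        h = self.body.forward(x, training=training, rng=rng)
        self._head_out = h
        return self.output.forward(h, training=training, rng=rng)

    def predict_proba(self, x, batch_size: int = 4096) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(self.forward(x[i:i + batch_size], training=False))
        return np.concatenate(out)

    def backward_from_logit_grad(self, dz):
        dh = self.output.backward_from_logit_grad(dz)
        self.body.backward(dh)

    def penultimate_features(self, x, batch_size: int = 4096) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            self.forward(x[i:i + batch_size], training=False)
            out.append(self._head_out.copy())
        return np.concatenate(out)


@dataclass(frozen=True)
class ParameterCount:
    total: int          # includes batch-norm running statistics
    trainable: int

    @property
    def non_trainable(self) -> int:
        return self.total - self.trainable


def count_parameters(model) -> ParameterCount:
    """Standard model-summary accounting: total (trainable plus
    non-trainable normalization statistics) and trainable-only counts."""
    params = model.all_params() if hasattr(model, "all_params") else model
    total = sum(p.value.size for p in params)
    trainable = sum(p.value.size for p in params if p.trainable)
    return ParameterCount(total, trainable)


def reported_parameter_count(model) -> int:
    """The count under the accounting convention resolved for this model
    (recorded in ``model.metadata['count_convention']``)."""
    pc = count_parameters(model)
    kind = model.metadata.get("count_convention", "total")
    return pc.total if kind == "total" else pc.trainable


class Adam:
    """Adam with optional L2 weight decay applied to convolution kernels."""

    def __init__(self, params: List[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 conv_l2: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.conv_l2 = conv_l2
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.conv_l2 and p.kind == "conv_kernel":
                g = g + 2.0 * self.conv_l2 * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.value = p.value - self.lr * mh / (np.sqrt(vh) + self.eps)
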