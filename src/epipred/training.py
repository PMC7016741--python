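"""Imbalance-aware training protocol.

Models are trained with a weighted binary cross-entropy whose class
weights equal (N/2)/n_class computed on the training partition, Adam with
the per-model batch size and learning rate, L2 weight decay on convolution
kernels only, and early stopping on validation F1 with patience 10 (ties
count as non-improvement; the earlier snapshot is kept). Alternatively the
minority class can be oversampled (or the majority class down-sampled) to
a 1:1 batch mix instead of weighting the loss.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .models import TrainingConfig
from .nn import Adam
from .types import ClassWeights, EpochRecord, TrainState

EPS = 1e-7
PATIENCE = 10
MAX_EPOCHS = 100

Inputs = Union[np.ndarray, Tuple[np.ndarray, ...]]


def class_weights(n_pos: int, n_neg: int) -> ClassWeights:
    """w_c = ((n_pos + n_neg)/2) / n_c, so each class's expected total loss
    contribution is equal for any class ratio."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes must be present to compute weights")
    half = (n_pos + n_neg) / 2.0
    return ClassWeights(w_pos=half / n_pos, w_neg=half / n_neg)


def weighted_bce(p: np.ndarray, y: np.ndarray,
                 w: Optional[ClassWeights] = None) -> float:
    """Batch-averaged -[w_pos*y*log(p) + w_neg*(1-y)*log(1-p)], with p
    clipped at machine tolerance."""
    p = np.clip(np.asarray(p, dtype=np.float64), EPS, 1.0 - EPS)
    y = np.asarray(y, dtype=np.float64)
    wp = 1.0 if w is None else w.w_pos
    wn = 1.0 if w is None else w.w_neg
    per = -(wp * y * np.log(p) + wn * (1.0 - y) * np.log1p(-p))
    return float(per.mean())


def f1_score(p: np.ndarray, y: np.ndarray, threshold: float = 0.5) -> float:
    """Harmonic mean of precision and recall of thresholded predictions;
    0 when positives exist but none are predicted."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    pred = np.asarray(p) >= threshold
    y = np.asarray(y).astype(bool)
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2.0 * precision * recall / (precision + recall)


def _as_tuple(x: Inputs) -> Tuple[np.ndarray, ...]:
    return x if isinstance(x, tuple) else (x,)


def _take(x: Inputs, idx) -> Tuple[np.ndarray, ...]:
    return tuple(a[idx] for a in _as_tuple(x))


def _forward(model, inputs: Tuple[np.ndarray, ...], training, rng):
    return model.forward(*inputs, training=training, rng=rng)


def _predict(model, x: Inputs) -> np.ndarray:
    return model.predict_proba(*_as_tuple(x))


def _rebalance_indices(y: np.ndarray, mode: str, rng) -> np.ndarray:
    """1:1 index resampling: oversample positives or down-sample negatives."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        return np.arange(len(y))
    if mode == "oversample":
        pos = rng.choice(pos, size=len(neg), replace=True)
    elif mode == "downsample":
        neg = rng.choice(neg, size=len(pos), replace=len(neg) < len(pos))
    idx = np.concatenate([pos, neg])
    rng.shuffle(idx)
    return idx


def train(model, train_data: Tuple[Inputs, np.ndarray],
          val_data: Tuple[Inputs, np.ndarray],
          config: TrainingConfig,
          weighting: str = "weighted_loss",
          seed: int = 0,
          max_epochs: int = MAX_EPOCHS,
          patience: int = PATIENCE,
          compute_val_auroc: bool = False) -> TrainState:
    """Train ``model`` in place; returns the TrainState and restores the
    snapshot with the highest validation F1."""
    if weighting not in ("weighted_loss", "oversample", "downsample"):
        raise ValueError(f"unknown weighting mode {weighting!r}")
    X_train, y_train = train_data
    X_val, y_val = val_data
    y_train = np.asarray(y_train, dtype=np.float64)
    y_val = np.asarray(y_val, dtype=np.float64)
    if len(y_train) == 0:
        raise ValueError("empty training partition")
    if len(y_val) == 0:
        raise ValueError("empty validation partition")

    n_pos = int(y_train.sum())
    n_neg = len(y_train) - n_pos
    if weighting == "weighted_loss" and n_pos > 0 and n_neg > 0:
        cw = class_weights(n_pos, n_neg)
    else:
        cw = ClassWeights(1.0, 1.0)

    rng = np.random.default_rng(seed)
    opt = Adam(model.trainable_params(), lr=config.learning_rate,
               conv_l2=config.conv_l2)

    best_f1 = -np.inf
    best_epoch = 0
    best_snap = model.snapshot()
    since_improve = 0
    state = TrainState(best_epoch=0, best_val_f1=0.0)

    for epoch in range(1, max_epochs + 1):
        if weighting == "weighted_loss":
            order = rng.permutation(len(y_train))
        else:
            order = _rebalance_indices(y_train, weighting, rng)
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb = _take(X_train, idx)
            yb = y_train[idx]
            p = _forward(model, xb, True, rng)
            loss = weighted_bce(p, yb, cw)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i // config.batch_size}: "
                    f"loss={loss}, p range [{p.min()}, {p.max()}]")
            losses.append(loss)
            # d(weighted BCE)/d(logit) for the sigmoid/softmax output
            pc = np.clip(p, EPS, 1.0 - EPS)
            w = np.where(yb == 1, cw.w_pos, cw.w_neg)
            dz = w * (pc - yb) / len(yb)
            model.backward_from_logit_grad(dz)
            opt.step()

        p_val = _predict(model, X_val)
        vf1 = f1_score(p_val, y_val)
        v_auc = None
        if compute_val_auroc and len(np.unique(y_val)) == 2:
            from .evaluation import auroc
            v_auc = auroc(p_val, y_val)
        state.history.append(EpochRecord(epoch, float(np.mean(losses)), vf1, v_auc))

        if vf1 > best_f1:
            best_f1 = vf1
            best_epoch = epoch
            best_snap = model.snapshot()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= patience:
                state.stopped_early = True
                break

    model.restore(best_snap)
    state.best_epoch = best_epoch
    state.best_val_f1 = float(max(best_f1, 0.0))
    return state
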