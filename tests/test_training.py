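"""Training-protocol semantics: class weighting, the weighted objective,
initialization bounds, F1, early stopping and determinism."""

import numpy as np
import pytest

from epipred.models import TrainingConfig, build_fnn
from epipred.nn import glorot_uniform_bounds
from epipred.training import (class_weights, f1_score, train, weighted_bce)
from epipred.types import ClassWeights


# ---------------------------------------------------------------------------
# class weights
# ---------------------------------------------------------------------------

def test_class_weights_balanced():
    w = class_weights(100, 100)
    assert w.w_pos == w.w_neg == 1.0


def test_class_weights_published_counts():
    # the study's K562 counts: 1977 positives, 39,500 negatives
    w = class_weights(1977, 39_500)
    assert np.isclose(w.w_pos, 20_738.5 / 1977)
    assert np.isclose(w.w_neg, 20_738.5 / 39_500)
    # balance identity: w_pos*n_pos + w_neg*n_neg = N
    assert np.isclose(w.w_pos * 1977 + w.w_neg * 39_500, 41_477)


def test_class_weights_scale_invariant():
    a = class_weights(10, 200)
    b = class_weights(30, 600)
    assert np.isclose(a.w_pos, b.w_pos) and np.isclose(a.w_neg, b.w_neg)


def test_class_weights_zero_count_raises():
    with pytest.raises(ValueError):
        class_weights(0, 10)


def test_balance_identity_expected_loss():
    # each class's expected total loss contribution is equal for any ratio
    rng = np.random.default_rng(0)
    n_pos, n_neg = 37, 613
    w = class_weights(n_pos, n_neg)
    p = np.full(n_pos + n_neg, 0.5)
    y = np.array([1] * n_pos + [0] * n_neg)
    pos_total = w.w_pos * n_pos * np.log(2)
    neg_total = w.w_neg * n_neg * np.log(2)
    assert np.isclose(pos_total, neg_total)
    assert np.isclose(weighted_bce(p, y, w), np.log(2))


# ---------------------------------------------------------------------------
# weighted BCE
# ---------------------------------------------------------------------------

def test_bce_perfect_prediction():
    assert weighted_bce(np.array([1.0]), np.array([1])) < 1e-6


def test_bce_half_is_log2():
    assert np.isclose(weighted_bce(np.array([0.5]), np.array([1])), np.log(2))


def test_bce_positive_term_linear_in_weight():
    p = np.array([0.3])
    y = np.array([1])
    l1 = weighted_bce(p, y, ClassWeights(1.0, 1.0))
    l2 = weighted_bce(p, y, ClassWeights(2.0, 1.0))
    assert np.isclose(l2, 2 * l1)


def test_bce_equal_weights_equal_unweighted():
    rng = np.random.default_rng(1)
    p = rng.uniform(0.01, 0.99, 50)
    y = rng.integers(0, 2, 50)
    assert np.isclose(weighted_bce(p, y, ClassWeights(1.0, 1.0)),
                      weighted_bce(p, y, None))


def test_bce_handles_saturated_probabilities():
    assert np.isfinite(weighted_bce(np.array([0.0, 1.0]), np.array([1, 0])))


# ---------------------------------------------------------------------------
# glorot bounds
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fi,fo,expected", [(3, 3, 1.0), (12, 12, 0.5)])
def test_glorot_bounds_examples(fi, fo, expected):
    lo, hi = glorot_uniform_bounds(fi, fo)
    assert np.isclose(hi, expected) and np.isclose(lo, -expected)


def test_glorot_bounds_invalid():
    with pytest.raises(ValueError):
        glorot_uniform_bounds(0, 5)


def test_glorot_sample_variance():
    # var of U(-b, b) is b^2/3 = 2/(fan_in + fan_out)
    rng = np.random.default_rng(2)
    fi, fo = 30, 70
    lo, hi = glorot_uniform_bounds(fi, fo)
    draws = rng.uniform(lo, hi, 1_000_000)
    assert np.isclose(draws.var(), 2.0 / (fi + fo), rtol=0.01)


# ---------------------------------------------------------------------------
# F1
# ---------------------------------------------------------------------------

def test_f1_values():
    assert f1_score(np.array([0.9, 0.1]), np.array([1, 0])) == 1.0
    assert f1_score(np.array([0.1, 0.2]), np.array([1, 0])) == 0.0
    # 2 TP, 1 FP, 1 FN -> 2/3
    p = np.array([0.9, 0.8, 0.7, 0.2])
    y = np.array([1, 1, 0, 1])
    assert np.isclose(f1_score(p, y), 2 / 3)


def test_f1_threshold_validation():
    with pytest.raises(ValueError):
        f1_score(np.array([0.5]), np.array([1]), threshold=1.5)


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

def _toy_data(n=300, sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n).astype(float)
    X = rng.standard_normal((n, 8)) + sep * y[:, None] * np.ones(8) / np.sqrt(8)
    return X, y


CFG = TrainingConfig(batch_size=50, learning_rate=1e-3, conv_l2=0.0)


def test_early_stop_on_flat_validation_f1():
    # an all-negative validation set pins F1 at 0; ties are non-improvement,
    # so training halts exactly after the patience window
    X, y = _toy_data()
    Xv = np.random.default_rng(1).standard_normal((40, 8))
    yv = np.zeros(40)
    m = build_fnn(8, hidden=(16, 8))
    st = train(m, (X, y), (Xv, yv), CFG, seed=0, max_epochs=50, patience=10)
    assert st.stopped_early
    assert len(st.history) == 11          # 1 best + 10 non-improving
    assert st.best_epoch == 1


def test_no_early_stop_while_improving():
    X, y = _toy_data(sep=4.0)
    m = build_fnn(8, hidden=(16, 8))
    st = train(m, (X[:200], y[:200]), (X[200:], y[200:]), CFG, seed=0,
               max_epochs=12, patience=10)
    assert st.best_val_f1 > 0.6
    assert not st.stopped_early


def test_best_snapshot_restored():
    X, y = _toy_data(sep=4.0)
    m = build_fnn(8, hidden=(16, 8))
    st = train(m, (X[:200], y[:200]), (X[200:], y[200:]), CFG, seed=0,
               max_epochs=20)
    from epipred.training import f1_score as f1
    assert np.isclose(f1(m.predict_proba(X[200:]), y[200:]), st.best_val_f1)


def test_seed_determinism_of_loss_trajectory():
    X, y = _toy_data()
    runs = []
    for _ in range(2):
        m = build_fnn(8, hidden=(16, 8), seed=7)
        st = train(m, (X[:200], y[:200]), (X[200:], y[200:]), CFG, seed=13,
                   max_epochs=5, patience=10)
        runs.append([r.train_loss for r in st.history])
    assert runs[0] == runs[1]


def test_loss_decreases_on_separable_data():
    X, y = _toy_data(sep=4.0)
    m = build_fnn(8, hidden=(16, 8))
    st = train(m, (X[:200], y[:200]), (X[200:], y[200:]), CFG, seed=0,
               max_epochs=8, patience=10)
    losses = [r.train_loss for r in st.history]
    assert losses[-1] < losses[0]


@pytest.mark.parametrize("mode", ["oversample", "downsample"])
def test_resampling_modes_learn(mode):
    X, y = _toy_data(n=400, sep=4.0, seed=3)
    m = build_fnn(8, hidden=(16, 8))
    st = train(m, (X[:300], y[:300]), (X[300:], y[300:]), CFG,
               weighting=mode, seed=0, max_epochs=10, patience=10)
    assert st.best_val_f1 > 0.7


def test_rebalance_indices_are_one_to_one():
    from epipred.training import _rebalance_indices
    rng = np.random.default_rng(0)
    y = np.array([1] * 5 + [0] * 95)
    idx = _rebalance_indices(y, "oversample", rng)
    assert np.isclose(y[idx].mean(), 0.5, atol=0.01)
    idx = _rebalance_indices(y, "downsample", rng)
    assert y[idx].mean() == 0.5


def test_empty_partitions_raise():
    X, y = _toy_data()
    m = build_fnn(8, hidden=(16, 8))
    with pytest.raises(ValueError, match="empty"):
        train(m, (X[:0], y[:0]), (X, y), CFG)
    with pytest.raises(ValueError, match="empty"):
        train(m, (X, y), (X[:0], y[:0]), CFG)


def test_nonfinite_loss_aborts_with_diagnostics():
    X, y = _toy_data()
    m = build_fnn(8, hidden=(16, 8))
    m.all_params()[0].value[:] = np.nan
    with pytest.raises(RuntimeError, match="non-finite"):
        train(m, (X, y), (X, y), CFG, max_epochs=1)


def test_unknown_weighting_mode():
    X, y = _toy_data()
    m = build_fnn(8, hidden=(16, 8))
    with pytest.raises(ValueError, match="weighting"):
        train(m, (X, y), (X, y), CFG, weighting="smote")
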