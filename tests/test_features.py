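"""Featurization arithmetic: per-base merging, window extraction,
sliding-window summaries, one-hot encoding and sequence matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import epipred as ep
from epipred.features import (central_crop, extract_window, match_sequence,
                              merge_intervals_to_per_base, one_hot_encode,
                              region_mean, sliding_window_mean)
from epipred.types import GenomicInterval


# ---------------------------------------------------------------------------
# merge_intervals_to_per_base
# ---------------------------------------------------------------------------

def brute_force_merge(records, length):
    vals = [[] for _ in range(length)]
    for s, e, v in records:
        for i in range(s, e):
            vals[i].append(v)
    return np.array([np.mean(v) if v else 0.0 for v in vals])


def test_merge_single_record():
    out = merge_intervals_to_per_base([(0, 10, 3.0)], 20)
    assert np.array_equal(out[:10], np.full(10, 3.0))
    assert np.array_equal(out[10:], np.zeros(10))


def test_merge_overlap_mean():
    out = merge_intervals_to_per_base([(0, 10, 2.0), (5, 15, 4.0)], 20)
    assert out[7] == 3.0
    assert out[2] == 2.0
    assert out[12] == 4.0


def test_merge_against_brute_force():
    rng = np.random.default_rng(0)
    records = [(int(s), int(s + w), float(v))
               for s, w, v in zip(rng.integers(0, 180, 50),
                                  rng.integers(1, 20, 50),
                                  rng.normal(size=50))]
    out = merge_intervals_to_per_base(records, 200)
    assert np.allclose(out, brute_force_merge(records, 200), atol=1e-12)


@pytest.mark.parametrize("records,err", [
    ([(0, 25, 1.0)], "exceeds"),
    ([(-1, 5, 1.0)], "negative"),
    ([(5, 5, 1.0)], "empty"),
])
def test_merge_errors(records, err):
    with pytest.raises(ValueError, match=err):
        merge_intervals_to_per_base(records, 20)


# ---------------------------------------------------------------------------
# extract_window
# ---------------------------------------------------------------------------

def test_extract_window_out_of_bounds_names_pair():
    track = np.zeros(4000)
    with pytest.raises(ValueError, match="chr1:1000-1010"):
        extract_window(track, GenomicInterval("chr1", 1000, 1010), 3000)


def test_extract_window_constant():
    track = np.full(9000, 7.5)
    w = extract_window(track, GenomicInterval("chr1", 5000, 5010), 2000)
    assert w.shape == (2000,)
    assert np.all(w == 7.5)


@pytest.mark.parametrize("start,end", [(5000, 5010), (5000, 5011)])
def test_extract_window_center_convention(start, end):
    # center = floor((start+end)/2) for both parities of element length
    track = np.arange(12000, dtype=float)
    center = (start + end) // 2
    w = extract_window(track, GenomicInterval("chr1", start, end), 2000)
    assert w[0] == center - 1000
    assert w[-1] == center + 999


# ---------------------------------------------------------------------------
# sliding_window_mean / region_mean
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("L,expected", [(3000, 296), (2000, 196)])
def test_sliding_window_counts(L, expected):
    out = sliding_window_mean(np.zeros((L, 22)), 50, 10)
    assert out.shape == (expected, 22)


def test_sliding_window_single_row_is_column_mean():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(50, 5))
    out = sliding_window_mean(x, 50, 10)
    assert out.shape == (1, 5)
    assert np.allclose(out[0], x.mean(axis=0))


def test_sliding_window_window_too_large():
    with pytest.raises(ValueError, match="exceeds"):
        sliding_window_mean(np.zeros((40, 2)), 50, 10)


def test_sliding_window_reduces_to_region_mean():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(120, 4))
    assert np.allclose(sliding_window_mean(x, 120, 120)[0], region_mean(x))


def test_region_mean_constant_and_oracle():
    assert np.allclose(region_mean(np.full((100, 3), 2.5)), 2.5)
    rng = np.random.default_rng(3)
    x = rng.normal(size=(3000, 22))
    assert np.allclose(region_mean(x), x.mean(axis=0), atol=1e-12)


def test_region_mean_empty_raises():
    with pytest.raises(ValueError):
        region_mean(np.zeros((0, 3)))


def test_targetfinder_vector_length(small_ds):
    X = ep.targetfinder_format(small_ds)
    assert X.shape[1] == 2 * small_ds.provenance.n_tracks == 44


def test_constant_input_formats_agree():
    # on constant signal, CNN-format and TargetFinder-format are the same constant
    x = np.full((3000, 22), 1.25)
    assert np.allclose(sliding_window_mean(x, 50, 10), 1.25)
    assert np.allclose(region_mean(x), 1.25)


@settings(deadline=None, max_examples=25)
@given(st.integers(51, 400), st.integers(1, 50), st.integers(1, 25))
def test_sliding_window_shape_formula(L, window, step):
    out = sliding_window_mean(np.zeros((L, 2)), window, step)
    assert out.shape[0] == (L - window) // step + 1


# ---------------------------------------------------------------------------
# one-hot / crops / matching
# ---------------------------------------------------------------------------

def test_one_hot_identity():
    assert np.array_equal(one_hot_encode("ACGT"), np.eye(4))


def test_one_hot_n_rows_zero():
    assert np.array_equal(one_hot_encode("NN"), np.zeros((2, 4)))


def test_one_hot_invalid_base():
    with pytest.raises(ValueError, match="'X'"):
        one_hot_encode("ACXG")


@settings(deadline=None, max_examples=20)
@given(st.text(alphabet="ACGTacgt", min_size=1, max_size=3000))
def test_one_hot_row_sums(seq):
    assert np.all(one_hot_encode(seq).sum(axis=1) == 1)


def test_central_crop_offsets():
    x = np.arange(3000 * 4).reshape(3000, 4)
    c = central_crop(x, 600)
    assert np.array_equal(c, x[1200:1800])
    assert np.array_equal(central_crop(x, 3000), x)
    with pytest.raises(ValueError):
        central_crop(x, 3001)


def test_central_crop_motif_survival():
    # a motif at the sequence center survives cropping; one at position 0 does not
    seq = list("A" * 3000)
    seq[1495:1505] = list("TGACGTCATG")
    oh = one_hot_encode("".join(seq))
    crop = central_crop(oh, 600)
    assert crop.sum(axis=0)[3] > 0          # T present in the crop
    seq2 = "TGACGTCATG" + "A" * 2990
    crop2 = central_crop(one_hot_encode(seq2), 600)
    assert crop2.sum(axis=0)[3] == 0


def test_match_sequence():
    ref = {"chr1": "AAACGTACGTTT"}
    iv = GenomicInterval("chr1", 3, 9)
    sub = ref["chr1"][3:9]
    assert match_sequence(iv, ref, ["TTTTTT", sub, "ACGTAC"]) == 1
    assert match_sequence(iv, ref, []) is None
    mutated = "A" + sub[1:]
    assert match_sequence(iv, ref, [mutated]) is None
    with pytest.raises(ValueError, match="ambiguous"):
        match_sequence(iv, ref, [sub, sub])


def test_cnn_format_shapes(small_ds):
    e, p = ep.cnn_format(small_ds)
    assert e.shape[1:] == (296, 22)
    assert p.shape[1:] == (196, 22)
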