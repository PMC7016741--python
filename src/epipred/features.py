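"""Turning interval/signal/sequence inputs into model-ready features.

Two epigenomic feature formats are produced from the same per-base signal:

- CNN-format: sliding-window means (window 50 bp, step 10 bp) over the
  3000/2000 bp windows centered on each element, giving 296 x n_tracks
  (enhancer) and 196 x n_tracks (promoter) matrices;
- TargetFinder-format: one mean per track per element region, giving a
  2 * n_tracks (44 for 22 assays) feature vector per pair.

Sequence features are one-hot matrices (channel order A, C, G, T; N rows
are all-zero), optionally centrally cropped to 600/400 bp.

All coordinates are 0-based half-open; windows are centered at
floor((start + end) / 2) and out-of-bounds windows are hard errors so
feature dimensions are always exact.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .types import (EPPair, GenomicInterval, SignalTrackSet, SyntheticDataset,
                    ENHANCER_WINDOW, PROMOTER_WINDOW)

WINDOW_BP = 50
STEP_BP = 10


# ---------------------------------------------------------------------------
# per-base signal assembly
# ---------------------------------------------------------------------------

def merge_intervals_to_per_base(records: Iterable[Tuple[int, int, float]],
                                chrom_length: int) -> np.ndarray:
    """Collapse interval-signal records on one chromosome to per-base values.

    Each base's value is the mean of all interval values covering it;
    uncovered bases are 0. Useful when the same base is measured in
    several overlapping sub-region samples.
    """
    total = np.zeros(chrom_length, dtype=np.float64)
    count = np.zeros(chrom_length, dtype=np.int64)
    for start, end, value in records:
        if start < 0:
            raise ValueError(f"negative interval start {start}")
        if end > chrom_length:
            raise ValueError(
                f"interval [{start}, {end}) exceeds chromosome length "
                f"{chrom_length}")
        if end <= start:
            raise ValueError(f"empty interval [{start}, {end})")
        total[start] += value
        if end < chrom_length:
            total[end] -= value
        count[start] += 1
        if end < chrom_length:
            count[end] -= 1
    total = np.cumsum(total)
    count = np.cumsum(count)
    out = np.zeros(chrom_length, dtype=np.float64)
    covered = count > 0
    out[covered] = total[covered] / count[covered]
    return out


def extract_window(track: np.ndarray, anchor: GenomicInterval,
                   width: int) -> np.ndarray:
    """Signal over [center - width/2, center + width/2) where center is
    floor((start + end) / 2). Errors identify the offending anchor."""
    center = anchor.center
    s = center - width // 2
    e = s + width
    if s < 0 or e > track.shape[0]:
        raise ValueError(
            f"window [{s}, {e}) for anchor {anchor.chrom}:{anchor.start}-"
            f"{anchor.end} lies outside the chromosome (length {track.shape[0]})")
    return track[s:e]


def sliding_window_mean(signal: np.ndarray, window: int = WINDOW_BP,
                        step: int = STEP_BP) -> np.ndarray:
    """W x T matrix of window means, W = floor((L - window)/step) + 1."""
    if signal.ndim == 1:
        signal = signal[:, None]
    L = signal.shape[0]
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    if window > L:
        raise ValueError(f"window {window} exceeds signal length {L}")
    csum = np.concatenate([np.zeros((1, signal.shape[1])),
                           np.cumsum(signal, axis=0, dtype=np.float64)])
    W = (L - window) // step + 1
    starts = np.arange(W) * step
    return (csum[starts + window] - csum[starts]) / window


def region_mean(signal: np.ndarray) -> np.ndarray:
    """Per-track arithmetic mean over all bases of the window."""
    if signal.shape[0] == 0:
        raise ValueError("cannot take the mean of an empty region")
    if signal.ndim == 1:
        signal = signal[:, None]
    return signal.mean(axis=0, dtype=np.float64)


# ---------------------------------------------------------------------------
# sequence encoding
# ---------------------------------------------------------------------------

_LUT = np.full(256, -2, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _LUT[b] = i
    _LUT[b + 32] = i          # lower case
_LUT[ord("N")] = -1
_LUT[ord("n")] = -1


def one_hot_encode(seq: str) -> np.ndarray:
    """L x 4 one-hot matrix, channel order A, C, G, T; N rows all-zero."""
    codes = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == -2).any():
        bad = seq[int(np.flatnonzero(codes == -2)[0])]
        raise ValueError(f"invalid base {bad!r} in sequence")
    out = np.zeros((len(seq), 4), dtype=np.float32)
    valid = codes >= 0
    out[np.flatnonzero(valid), codes[valid]] = 1.0
    return out


def central_crop(onehot: np.ndarray, target: int) -> np.ndarray:
    """The central ``target`` rows, offset floor((L - target)/2)."""
    L = onehot.shape[0]
    if target > L:
        raise ValueError(f"crop {target} exceeds length {L}")
    off = (L - target) // 2
    return onehot[off:off + target]


def match_sequence(pair_interval: GenomicInterval,
                   reference: Union[Dict[str, str], "object"],
                   candidates: Sequence[str]) -> Optional[int]:
    """Index of the unique candidate exactly equal to the reference
    substring at ``pair_interval``, or None. Multiple exact matches raise
    (ambiguous match)."""
    if hasattr(reference, "keys") and isinstance(reference, dict):
        ref = reference[pair_interval.chrom][pair_interval.start:pair_interval.end]
    else:  # pyfaidx.Fasta-like store
        ref = str(reference[pair_interval.chrom][pair_interval.start:pair_interval.end])
    hits = [i for i, c in enumerate(candidates) if c == ref]
    if len(hits) > 1:
        raise ValueError(f"ambiguous match: candidates {hits} all equal the "
                         f"reference at {pair_interval.chrom}:"
                         f"{pair_interval.start}-{pair_interval.end}")
    return hits[0] if hits else None


# ---------------------------------------------------------------------------
# dataset-level featurization
# ---------------------------------------------------------------------------

def _pair_windows(tracks: SignalTrackSet, pair: EPPair,
                  enhancer_len: int, promoter_len: int):
    arr = tracks.values[pair.chrom]
    we = extract_window(arr, pair.enhancer, enhancer_len)
    wp = extract_window(arr, pair.promoter, promoter_len)
    return we, wp


def cnn_format(dataset: SyntheticDataset,
               window: int = WINDOW_BP, step: int = STEP_BP
               ) -> Tuple[np.ndarray, np.ndarray]:
    """(n, 296, T) enhancer and (n, 196, T) promoter sliding-window means."""
    cfg = dataset.provenance
    es, ps = [], []
    for pair in dataset.pairs:
        we, wp = _pair_windows(dataset.tracks, pair, cfg.enhancer_len,
                               cfg.promoter_len)
        es.append(sliding_window_mean(we, window, step))
        ps.append(sliding_window_mean(wp, window, step))
    return (np.asarray(es, dtype=np.float32),
            np.asarray(ps, dtype=np.float32))


def targetfinder_format(dataset: SyntheticDataset) -> np.ndarray:
    """(n, 2T) region means: T enhancer means then T promoter means."""
    cfg = dataset.provenance
    out = []
    for pair in dataset.pairs:
        we, wp = _pair_windows(dataset.tracks, pair, cfg.enhancer_len,
                               cfg.promoter_len)
        out.append(np.concatenate([region_mean(we), region_mean(wp)]))
    return np.asarray(out, dtype=np.float32)


def sequence_format(dataset: SyntheticDataset,
                    crop: Optional[Tuple[int, int]] = None
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """One-hot (n, 3000, 4)/(n, 2000, 4) sequence pairs, optionally
    centrally cropped to e.g. (600, 400)."""
    cfg = dataset.provenance
    es, ps = [], []
    for pair in dataset.pairs:
        seq = dataset.sequences[pair.chrom]
        for iv, width, sink in ((pair.enhancer, cfg.enhancer_len, es),
                                (pair.promoter, cfg.promoter_len, ps)):
            c = iv.center
            s = c - width // 2
            if s < 0 or s + width > len(seq):
                raise ValueError(f"sequence window out of bounds for "
                                 f"{iv.chrom}:{iv.start}-{iv.end}")
            oh = one_hot_encode(seq[s:s + width])
            if crop is not None:
                oh = central_crop(oh, crop[0] if sink is es else crop[1])
            sink.append(oh)
    return (np.asarray(es, dtype=np.float32),
            np.asarray(ps, dtype=np.float32))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_pair_table(path: str) -> List[EPPair]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            pairs.append(EPPair(
                GenomicInterval(f[0], int(f[1]), int(f[2])),
                GenomicInterval(f[3], int(f[4]), int(f[5])),
                int(f[6]), f[7], f[8]))
    return pairs


def read_bedgraph(path: str) -> Dict[str, List[Tuple[int, int, float]]]:
    """bedGraph-dialect text -> per-chromosome interval-signal records."""
    out: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split()[:4]
            out.setdefault(chrom, []).append((int(s), int(e), float(v)))
    return out


def read_bedgraph_tracks(paths: Sequence[str], chrom_lengths: Dict[str, int],
                         assays: Optional[Sequence[str]] = None,
                         dtype=np.float32) -> SignalTrackSet:
    """Assemble a SignalTrackSet from one bedGraph file per assay."""
    if assays is None:
        assays = tuple(os.path.splitext(os.path.basename(p))[0] for p in paths)
    values = {c: np.zeros((L, len(paths)), dtype=dtype)
              for c, L in chrom_lengths.items()}
    for t, path in enumerate(paths):
        for chrom, records in read_bedgraph(path).items():
            per_base = merge_intervals_to_per_base(records, chrom_lengths[chrom])
            values[chrom][:, t] = per_base.astype(dtype)
    return SignalTrackSet(assays=tuple(assays), values=values)


def read_fasta(path: str) -> Dict[str, str]:
    seqs: Dict[str, List[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def read_bigwig_track(path: str, chrom: str, length: int) -> np.ndarray:
    """Optional BigWig adapter behind the same per-base-array contract."""
    import pyBigWig
    bw = pyBigWig.open(path)
    try:
        vals = np.array(bw.values(chrom, 0, length), dtype=np.float64)
    finally:
        bw.close()
    return np.nan_to_num(vals, nan=0.0)


def write_feature_hdf5(path: str, arrays: Dict[str, np.ndarray],
                       assays: Sequence[str]) -> None:
    """HDF5 container for feature tensors with assay-name metadata."""
    import h5py
    with h5py.File(path, "w") as h5:
        for k, v in arrays.items():
            h5.create_dataset(k, data=v, compression="gzip")
        h5.attrs["assays"] = list(assays)
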