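"""Synthetic EPI benchmark generator.

Emulates the statistical and structural properties of the real
TargetFinder/SPEID-style data that the analysis pipeline assumes:

- ~1:20 positive:negative class imbalance;
- enhancers and promoters reused across multiple pairs (so random
  splitting produces non-independent train/test sets);
- per-pair chromosome assignment over 23 named chromosomes of varying
  size (so per-chromosome test sets differ in size, exercising the
  weighted AUROC aggregation);
- 22 per-base signal tracks with peak-like autocorrelation (i.i.d.
  Gaussian noise smoothed with a 50 bp moving average around
  track-specific baselines) and an optional planted class-dependent mean
  shift inside positive elements' 3000/2000 bp windows;
- reference-style per-chromosome sequences with an optional fixed 10-mer
  motif planted in the central 600/400 bp of positive elements.

Negative pairs are random same-chromosome enhancer-promoter pairings at
distance > 10 kb, mirroring the focus on distal interactions.
"""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d

from .types import (ASSAY_NAMES, CHROMOSOMES, EPPair, GenomicInterval,
                    SignalTrackSet, SyntheticConfig, SyntheticDataset)

#: Fixed 10-mer planted in positive elements' central regions.
MOTIF = "TGACGTCATG"

#: Number of leading tracks that carry the planted epigenomic effect.
N_SIGNAL_TRACKS = 8

#: Smoothing window (bp) giving the noise peak-like autocorrelation.
SMOOTH_BP = 50

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def chromosome_lengths(config: SyntheticConfig) -> Dict[str, int]:
    """Fixed length table: autosome sizes decrease with chromosome number
    (floored so every chromosome can hold distal pairs); chrX mid-sized."""
    lengths = {}
    for i, chrom in enumerate(CHROMOSOMES[:config.n_chromosomes], start=1):
        units = 10 if chrom == "chrX" else max(24 - i, 3)
        lengths[chrom] = units * config.bp_per_unit
    return lengths


def _assay_names(n_tracks: int) -> Tuple[str, ...]:
    if n_tracks <= len(ASSAY_NAMES):
        return ASSAY_NAMES[:n_tracks]
    extra = tuple(f"assay{i}" for i in range(len(ASSAY_NAMES) + 1, n_tracks + 1))
    return ASSAY_NAMES + extra


def _element_regions(L: int, config: SyntheticConfig) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Center ranges for enhancers (left) and promoters (right) such that
    windows stay inside the chromosome and pair distance exceeds the
    distal threshold."""
    half = max(config.enhancer_len, config.promoter_len) // 2
    usable = L - 2 * half
    side = (usable - config.min_distance) // 2
    if usable <= 0 or side <= 0:
        raise ValueError(
            f"chromosome of length {L} cannot hold distal pairs with "
            f"window {2 * half} and min distance {config.min_distance}")
    return (half, half + side), (L - half - side, L - half)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a deterministic synthetic EPI dataset.

    Positive and negative pairs draw their elements from separate pools
    of size ~ n_class_pairs / duplication_factor per chromosome, so
    elements recur across pairs and element labels are consistent.
    """
    if config.n_pairs < config.imbalance_ratio + 1:
        raise ValueError(
            f"cannot realize ratio 1:{config.imbalance_ratio} with only "
            f"{config.n_pairs} pairs")
    rng = np.random.default_rng(config.seed)
    lengths = chromosome_lengths(config)
    chroms = list(lengths)
    assays = _assay_names(config.n_tracks)

    # --- labels and chromosome assignment -------------------------------
    p_pos = 1.0 / (1.0 + config.imbalance_ratio)
    labels = (rng.random(config.n_pairs) < p_pos).astype(np.int8)
    if labels.sum() == 0:
        labels[0] = 1
    if labels.sum() == config.n_pairs:
        labels[0] = 0
    sizes = np.array([lengths[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=config.n_pairs, p=sizes / sizes.sum())

    # --- element pools per (chromosome, class) ---------------------------
    elem_len_ranges = {"E": (200, 800), "P": (400, 1200)}
    sig_tracks = min(N_SIGNAL_TRACKS, config.n_tracks)
    signal_elements: List[Tuple[str, GenomicInterval]] = []
    motif_elements: List[Tuple[GenomicInterval, int]] = []
    pairs: List[Optional[EPPair]] = [None] * config.n_pairs

    for ci, chrom in enumerate(chroms):
        (e_lo, e_hi), (p_lo, p_hi) = _element_regions(lengths[chrom], config)
        for y in (1, 0):
            idx = np.flatnonzero((chrom_idx == ci) & (labels == y))
            m = len(idx)
            if m == 0:
                continue
            if config.duplication_factor == 1:
                pool_n = m
            else:
                pool_n = max(1, int(round(m / config.duplication_factor)))

            def make_pool(role, lo, hi, n):
                out = []
                lmin, lmax = elem_len_ranges[role]
                centers = rng.integers(lo, hi, size=n)
                elens = rng.integers(lmin, lmax + 1, size=n)
                for k in range(n):
                    c, el = int(centers[k]), int(elens[k])
                    iv = GenomicInterval(chrom, c - el // 2, c - el // 2 + el)
                    out.append((f"{role}{chrom[3:]}_{y}_{k}", iv))
                return out

            enh_pool = make_pool("E", e_lo, e_hi, pool_n)
            prom_pool = make_pool("P", p_lo, p_hi, pool_n)
            if y == 1:
                for role, pool in (("E", enh_pool), ("P", prom_pool)):
                    for _, iv in pool:
                        signal_elements.append((role, iv))
                        if (config.seq_motif_rate > 0
                                and rng.random() < config.seq_motif_rate):
                            motif_elements.append((iv, 600 if role == "E" else 400))
            if config.duplication_factor == 1:
                e_assign = rng.permutation(pool_n)
                p_assign = rng.permutation(pool_n)
            else:
                e_assign = rng.integers(0, pool_n, size=m)
                p_assign = rng.integers(0, pool_n, size=m)
            for j, pair_i in enumerate(idx):
                eid, e_iv = enh_pool[e_assign[j]]
                pid, p_iv = prom_pool[p_assign[j]]
                pairs[pair_i] = EPPair(e_iv, p_iv, int(y), eid, pid)

    # --- signal tracks ----------------------------------------------------
    baselines = 0.5 + 0.02 * np.arange(config.n_tracks, dtype=np.float32)
    values: Dict[str, np.ndarray] = {}
    for chrom in chroms:
        L = lengths[chrom]
        noise = rng.standard_normal((L, config.n_tracks)).astype(np.float32)
        noise *= np.float32(config.noise_sd)
        uniform_filter1d(noise, SMOOTH_BP, axis=0, mode="nearest", output=noise)
        values[chrom] = noise + baselines
    tracks = SignalTrackSet(assays=assays, values=values)

    if config.epi_effect > 0:
        for role, iv in signal_elements:
            w = (config.enhancer_len if role == "E" else config.promoter_len) // 2
            arr = values[iv.chrom]
            s, e = max(iv.center - w, 0), min(iv.center + w, arr.shape[0])
            arr[s:e, :sig_tracks] += np.float32(config.epi_effect)

    # --- sequences --------------------------------------------------------
    sequences: Dict[str, str] = {}
    seq_bytes: Dict[str, bytearray] = {}
    for chrom in chroms:
        codes = rng.integers(0, 4, size=lengths[chrom], dtype=np.uint8)
        seq_bytes[chrom] = bytearray(_BASES[codes].tobytes())
    for iv, crop in motif_elements:
        lo = iv.center - crop // 2
        off = int(rng.integers(0, crop - len(MOTIF) + 1))
        start = lo + off
        seq_bytes[iv.chrom][start:start + len(MOTIF)] = MOTIF.encode()
    for chrom in chroms:
        sequences[chrom] = seq_bytes[chrom].decode()

    return SyntheticDataset(pairs=list(pairs), tracks=tracks,
                            sequences=sequences, provenance=config)


def plant_leak_feature(dataset: SyntheticDataset, strength: float,
                       seed: Optional[int] = None) -> SyntheticDataset:
    """Add an element-identity-linked signal component.

    Every enhancer element receives a fixed random per-track offset vector,
    multiplied by +1/-1 according to the element's majority label and by
    ``strength``, over its enhancer window. Marginally over elements the
    offsets carry no class information (the fingerprint direction is
    random), so nothing generalizes to unseen elements; but any pair
    sharing an enhancer with a training pair exposes the memorizable
    fingerprint-label association. This is the leakage channel that
    inflates random-split evaluation.
    """
    if strength < 0:
        raise ValueError("leak strength must be >= 0")
    if strength == 0:
        return dataset
    cfg = dataset.provenance
    rng = np.random.default_rng(seed if seed is not None else cfg.seed + 997)
    values = {c: v.copy() for c, v in dataset.tracks.values.items()}

    by_element: Dict[str, Tuple[GenomicInterval, List[int]]] = {}
    for pair in dataset.pairs:
        iv, lab = by_element.setdefault(pair.enhancer_id, (pair.enhancer, []))
        lab.append(pair.label)
    half = cfg.enhancer_len // 2
    for eid in sorted(by_element):
        iv, labs = by_element[eid]
        sign = 1.0 if np.mean(labs) >= 0.5 else -1.0
        g = rng.standard_normal(cfg.n_tracks).astype(np.float32)
        arr = values[iv.chrom]
        s = max(iv.center - half, 0)
        e = min(iv.center + half, arr.shape[0])
        arr[s:e] += np.float32(strength * sign) * g

    tracks = SignalTrackSet(assays=dataset.tracks.assays, values=values)
    return SyntheticDataset(pairs=dataset.pairs, tracks=tracks,
                            sequences=dataset.sequences, provenance=cfg)


# ---------------------------------------------------------------------------
# writers (tab-separated pair tables, bedGraph-dialect tracks, FASTA)
# ---------------------------------------------------------------------------

def write_pair_table(pairs: List[EPPair], path: str) -> None:
    """BEDPE-like TSV: chrom, enh_start, enh_end, chrom, prom_start,
    prom_end, label, enhancer_id, promoter_id."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.enhancer.chrom}\t{p.enhancer.start}\t{p.enhancer.end}"
                     f"\t{p.promoter.chrom}\t{p.promoter.start}\t{p.promoter.end}"
                     f"\t{p.label}\t{p.enhancer_id}\t{p.promoter_id}\n")


def write_bedgraph_tracks(tracks: SignalTrackSet, outdir: str) -> List[str]:
    """One bedGraph-dialect file per assay (chrom, start, end, value),
    run-length encoded. Values are written with enough digits to
    round-trip float32 exactly."""
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for t, assay in enumerate(tracks.assays):
        path = os.path.join(outdir, f"{assay}.bedgraph")
        with open(path, "w") as fh:
            for chrom in tracks.values:
                col = tracks.values[chrom][:, t]
                change = np.flatnonzero(np.diff(col)) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(col)]])
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\t{col[s]:.9g}\n")
        paths.append(path)
    return paths


def write_fasta(sequences: Dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
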