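"""Core domain containers for enhancer-promoter interaction (EPI) prediction.

Coordinates are 0-based, half-open (BED convention) throughout. Every
candidate pair is intra-chromosomal: distal enhancers contact promoters on
the same chromosome through chromatin looping, so the pair's chromosome is
well defined and is the unit of held-out evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np

#: The 22 epigenomic assays used as signal tracks, in fixed column order:
#: 11 histone marks, 9 transcription-factor bindings, DNase accessibility
#: and DNA methylation. The order is recorded because it defines feature
#: column identity in every derived matrix.
ASSAY_NAMES: tuple = (
    "H3K27ac", "H3K27me3", "H3K4me1", "H2AZ", "H3K4me2", "H3K9ac",
    "H3K4me3", "H4K20me1", "H3K79me2", "H3K36me3", "H3K9me3",
    "POLR2A", "CTCF", "EP300", "MAFK", "MAZ", "MXI1", "RAD21",
    "RCOR1", "RFX5", "DNase", "Methylation",
)

#: Chromosome universe: 22 autosomes plus chrX. chrY is excluded by default
#: (the evaluation protocol accounts for 21 test chromosomes plus the two
#: fixed validation chromosomes chr8/chr9).
CHROMOSOMES: tuple = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)

ENHANCER_WINDOW = 3000
PROMOTER_WINDOW = 2000


def natural_chrom_key(chrom: str):
    """Sort key for chr1 < chr2 < ... < chr22 < chrX < chrY."""
    body = chrom[3:] if chrom.startswith("chr") else chrom
    if body.isdigit():
        return (0, int(body))
    return (1, {"X": 0, "Y": 1}.get(body, 2), body)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class EPPair:
    """An enhancer-promoter candidate pair with a binary interaction label.

    ``enhancer_id``/``promoter_id`` identify the underlying elements; they
    are shared whenever an element participates in several pairs, which is
    exactly the dependence structure that makes random train/test splitting
    leak information.
    """

    enhancer: GenomicInterval
    promoter: GenomicInterval
    label: int
    enhancer_id: str
    promoter_id: str

    def __post_init__(self):
        if self.enhancer.chrom != self.promoter.chrom:
            raise ValueError("EPI pairs are intra-chromosomal: "
                             f"{self.enhancer.chrom} != {self.promoter.chrom}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")

    @property
    def chrom(self) -> str:
        return self.enhancer.chrom


@dataclass
class SignalTrackSet:
    """Per-base signal for a set of named assays over named chromosomes.

    ``values[chrom]`` is a float32 array of shape (chrom_length, n_assays);
    missing bases are 0. Assay order is fixed and recorded in ``assays``.
    """

    assays: tuple
    values: Dict[str, np.ndarray]

    def chrom_length(self, chrom: str) -> int:
        return self.values[chrom].shape[0]

    @property
    def n_assays(self) -> int:
        return len(self.assays)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic EPI benchmark generator.

    Defaults mirror the real data structure: ~1:20 class imbalance,
    22 tracks, 23 named chromosomes, 3000/2000 bp windows and element
    reuse across pairs.
    """

    n_pairs: int = 2000
    imbalance_ratio: int = 20
    n_chromosomes: int = 23
    n_tracks: int = 22
    enhancer_len: int = ENHANCER_WINDOW
    promoter_len: int = PROMOTER_WINDOW
    epi_effect: float = 0.0
    seq_motif_rate: float = 0.0
    duplication_factor: float = 3.0
    noise_sd: float = 1.0
    min_distance: int = 10_000
    bp_per_unit: int = 7500
    seed: int = 0

    def __post_init__(self):
        for name in ("n_pairs", "imbalance_ratio", "n_chromosomes", "n_tracks",
                     "enhancer_len", "promoter_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.seq_motif_rate <= 1.0:
            raise ValueError("seq_motif_rate must lie in [0, 1]")
        if self.epi_effect < 0:
            raise ValueError("epi_effect must be >= 0")
        if self.duplication_factor < 1:
            raise ValueError("duplication_factor must be >= 1")


@dataclass
class SyntheticDataset:
    """A generated benchmark: pairs, genome-wide tracks and sequences."""

    pairs: List[EPPair]
    tracks: SignalTrackSet
    sequences: Dict[str, str]
    provenance: SyntheticConfig

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.pairs], dtype=np.int8)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([p.chrom for p in self.pairs])


@dataclass(frozen=True)
class SplitPlan:
    """A chromosome-held-out split: fixed validation chromosomes, one test
    chromosome, and all remaining chromosomes for training."""

    validation_chroms: frozenset
    test_chrom: str
    train_chroms: frozenset

    def __post_init__(self):
        if self.test_chrom in self.validation_chroms:
            raise ValueError("test chromosome cannot be a validation chromosome")
        overlap = self.train_chroms & (self.validation_chroms | {self.test_chrom})
        if overlap:
            raise ValueError(f"partitions overlap: {sorted(overlap)}")

    @property
    def universe(self) -> frozenset:
        return self.train_chroms | self.validation_chroms | {self.test_chrom}


@dataclass(frozen=True)
class ClassWeights:
    """Loss weights balancing expected per-class contributions."""

    w_pos: float
    w_neg: float


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_f1: float
    val_auroc: Optional[float]


@dataclass
class TrainState:
    """Outcome of a training run under the early-stopping protocol."""

    best_epoch: int
    best_val_f1: float
    history: List[EpochRecord] = field(default_factory=list)
    stopped_early: bool = False

    def summary(self) -> str:
        lines = ["epoch\ttrain_loss\tval_f1\tval_auroc"]
        for r in self.history:
            auc = "NA" if r.val_auroc is None else f"{r.val_auroc:.4f}"
            lines.append(f"{r.epoch}\t{r.train_loss:.6f}\t{r.val_f1:.4f}\t{auc}")
        lines.append(f"best epoch {self.best_epoch} (val F1 {self.best_val_f1:.4f}); "
                     f"early stop: {self.stopped_early}")
        return "\n".join(lines)
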