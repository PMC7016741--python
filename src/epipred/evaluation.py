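"""Chromosome-held-out evaluation, weighted AUROC aggregation, paired
t-tests, and the leakage-demonstration experiment.

Per-chromosome test AUROCs are aggregated with weights proportional to
each chromosome's pair count:

    mean = sum(w_i * a_i),   sd = sqrt(sum(w_i * (a_i - mean)^2)),
    w_i = n_i / sum(n_j)

(the weighted population standard deviation; an unweighted sample-SD
companion is also computed). Methods are compared with a paired two-sided
t-test across test chromosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from . import features as ft
from .models import TRAINING_CONFIGS, TrainingConfig, ZOO_BUILDERS, build_fnn
from .splits import assign_pairs, make_split_plans, random_split
from .training import train
from .types import SyntheticDataset, natural_chrom_key


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; equals the Mann-Whitney probability that
    a random positive outranks a random negative, ties counted 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores)))


def mann_whitney_null_se(n_pos: int, n_neg: int) -> float:
    """Standard error of AUROC under the null (no association):
    sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))."""
    return float(np.sqrt((n_pos + n_neg + 1) / (12.0 * n_pos * n_neg)))


@dataclass
class EvalSummary:
    """Per-chromosome AUROCs with chromosome-size-weighted aggregation."""

    per_chrom: Dict[str, Tuple[float, int]]
    excluded: List[str] = field(default_factory=list)

    @property
    def weights(self) -> np.ndarray:
        ns = np.array([n for _, n in self.per_chrom.values()], dtype=float)
        return ns / ns.sum()

    @property
    def aurocs(self) -> np.ndarray:
        return np.array([a for a, _ in self.per_chrom.values()])

    @property
    def weighted_mean(self) -> float:
        return float(self.weights @ self.aurocs)

    @property
    def weighted_sd(self) -> float:
        m = self.weighted_mean
        return float(np.sqrt(self.weights @ (self.aurocs - m) ** 2))

    @property
    def sample_sd(self) -> float:
        a = self.aurocs
        return float(a.std(ddof=1)) if len(a) > 1 else 0.0

    def ordered(self, chroms: Optional[Sequence[str]] = None) -> np.ndarray:
        keys = chroms if chroms is not None else sorted(self.per_chrom,
                                                       key=natural_chrom_key)
        return np.array([self.per_chrom[c][0] for c in keys])

    def summary(self) -> str:
        lines = ["chrom\tn\tauroc"]
        for c in sorted(self.per_chrom, key=natural_chrom_key):
            a, n = self.per_chrom[c]
            lines.append(f"{c}\t{n}\t{a:.4f}")
        lines.append(f"weighted mean {self.weighted_mean:.4f} "
                     f"(weighted sd {self.weighted_sd:.4f}, "
                     f"sample sd {self.sample_sd:.4f})")
        if self.excluded:
            lines.append(f"excluded (single-class test): {self.excluded}")
        return "\n".join(lines)


def weighted_summary(per_chrom: Sequence[Tuple[float, int]],
                     chroms: Optional[Sequence[str]] = None) -> EvalSummary:
    if len(per_chrom) == 0:
        raise ValueError("no per-chromosome results to aggregate")
    if any(n < 1 for _, n in per_chrom):
        raise ValueError("all sample counts must be >= 1")
    if chroms is None:
        chroms = [f"chr{i + 1}" for i in range(len(per_chrom))]
    return EvalSummary({c: (float(a), int(n))
                        for c, (a, n) in zip(chroms, per_chrom)})


@dataclass
class PairedComparison:
    """Two-sided paired t-test on per-chromosome AUROC differences."""

    differences: np.ndarray
    t_statistic: float
    p_value: float
    n: int
    degenerate: bool = False
    bonferroni_m: int = 1

    @property
    def p_bonferroni(self) -> float:
        return float(min(1.0, self.p_value * self.bonferroni_m))

    def summary(self) -> str:
        return (f"paired t-test over {self.n} chromosomes: mean diff "
                f"{self.differences.mean():+.4f}, t = {self.t_statistic:.3f}, "
                f"p = {self.p_value:.4g}"
                + (f" (Bonferroni x{self.bonferroni_m}: {self.p_bonferroni:.4g})"
                   if self.bonferroni_m > 1 else "")
                + (" [degenerate]" if self.degenerate else ""))


def paired_t_test(a: Sequence[float], b: Sequence[float],
                  bonferroni_m: int = 1) -> PairedComparison:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    if len(a) < 2:
        raise ValueError("paired t-test needs at least 2 chromosomes")
    d = a - b
    if np.allclose(d, 0.0):
        return PairedComparison(d, 0.0, 1.0, len(d), degenerate=True,
                                bonferroni_m=bonferroni_m)
    if np.isclose(d.std(ddof=1), 0.0):
        t = np.inf if d.mean() > 0 else -np.inf
        return PairedComparison(d, float(t), 0.0, len(d), degenerate=True,
                                bonferroni_m=bonferroni_m)
    t, p = stats.ttest_rel(a, b)
    return PairedComparison(d, float(t), float(p), len(d),
                            bonferroni_m=bonferroni_m)


# ---------------------------------------------------------------------------
# chromosome sweeps
# ---------------------------------------------------------------------------

def prepare_features(dataset: SyntheticDataset, feature_format: str,
                     crop: Optional[Tuple[int, int]] = (600, 400)):
    """Model-ready inputs for a whole dataset, as a tuple of arrays."""
    if feature_format == "targetfinder":
        return (ft.targetfinder_format(dataset),)
    if feature_format == "cnn":
        return ft.cnn_format(dataset)
    if feature_format == "sequence":
        return ft.sequence_format(dataset, crop=None)
    if feature_format == "sequence_crop":
        return ft.sequence_format(dataset, crop=crop)
    raise ValueError(f"unknown feature format {feature_format!r}")


def _default_builder(model_name: str, feature_format: str, X, seed: int):
    if model_name == "fnn":
        return build_fnn(input_dim=X[0].shape[1], seed=seed)
    builder = ZOO_BUILDERS[model_name]
    return builder(seed=seed)


def run_chromosome_sweep(dataset: SyntheticDataset,
                         model_name: str = "fnn",
                         feature_format: str = "targetfinder",
                         config: Optional[TrainingConfig] = None,
                         seed: int = 0,
                         builder: Optional[Callable[[int], object]] = None,
                         weighting: str = "weighted_loss",
                         max_epochs: int = 60,
                         features=None) -> EvalSummary:
    """Train/evaluate under every chromosome-held-out SplitPlan.

    ``builder(seed)`` may supply a custom (e.g. width-reduced) model; by
    default the zoo builder named ``model_name`` is used. Test chromosomes
    whose pairs are single-class are excluded with a warning.
    """
    if config is None:
        config = TRAINING_CONFIGS.get(model_name, TrainingConfig())
    X = features if features is not None else prepare_features(dataset,
                                                               feature_format)
    y = dataset.labels.astype(np.float64)
    chroms = sorted({p.chrom for p in dataset.pairs}, key=natural_chrom_key)
    plans = make_split_plans(chroms)
    per_chrom: Dict[str, Tuple[float, int]] = {}
    excluded: List[str] = []
    for k, plan in enumerate(plans):
        tr, va, te = assign_pairs(dataset.pairs, plan)
        if len(te) == 0 or len(np.unique(y[te])) < 2:
            excluded.append(plan.test_chrom)
            warnings.warn(f"test chromosome {plan.test_chrom} lacks both "
                          "classes; excluded from aggregation")
            continue
        model_seed = seed * 1009 + k
        model = (builder(model_seed) if builder is not None
                 else _default_builder(model_name, feature_format, X, model_seed))
        Xtr = tuple(a[tr] for a in X)
        Xva = tuple(a[va] for a in X)
        Xte = tuple(a[te] for a in X)
        train(model, (Xtr if len(Xtr) > 1 else Xtr[0], y[tr]),
              (Xva if len(Xva) > 1 else Xva[0], y[va]),
              config, weighting=weighting, seed=model_seed,
              max_epochs=max_epochs)
        scores = model.predict_proba(*Xte)
        per_chrom[plan.test_chrom] = (auroc(scores, y[te]), len(te))
    summary = EvalSummary(per_chrom, excluded=excluded)
    return summary


def run_random_split_eval(dataset: SyntheticDataset,
                          model_name: str = "fnn",
                          feature_format: str = "targetfinder",
                          config: Optional[TrainingConfig] = None,
                          seed: int = 0,
                          fractions=(0.8, 0.1, 0.1),
                          builder: Optional[Callable[[int], object]] = None,
                          weighting: str = "weighted_loss",
                          max_epochs: int = 60,
                          features=None) -> float:
    """Single random-split test AUROC (the known-biased scheme)."""
    if config is None:
        config = TRAINING_CONFIGS.get(model_name, TrainingConfig())
    X = features if features is not None else prepare_features(dataset,
                                                               feature_format)
    y = dataset.labels.astype(np.float64)
    tr, va, te = random_split(dataset.pairs, fractions, seed=seed)
    model = (builder(seed) if builder is not None
             else _default_builder(model_name, feature_format, X, seed))
    Xtr = tuple(a[tr] for a in X)
    Xva = tuple(a[va] for a in X)
    Xte = tuple(a[te] for a in X)
    train(model, (Xtr if len(Xtr) > 1 else Xtr[0], y[tr]),
          (Xva if len(Xva) > 1 else Xva[0], y[va]),
          config, weighting=weighting, seed=seed, max_epochs=max_epochs)
    return auroc(model.predict_proba(*Xte), y[te])


@dataclass
class LeakageResult:
    random_split_aurocs: List[float]
    chromosome_split_aurocs: List[float]
    comparison: PairedComparison

    @property
    def random_split_auroc(self) -> float:
        return float(np.mean(self.random_split_aurocs))

    @property
    def chromosome_split_auroc(self) -> float:
        return float(np.mean(self.chromosome_split_aurocs))

    def summary(self) -> str:
        return (f"random-split AUROC {self.random_split_auroc:.4f} vs "
                f"chromosome-split AUROC {self.chromosome_split_auroc:.4f}; "
                + self.comparison.summary())


def leakage_experiment(dataset: SyntheticDataset,
                       model_name: str = "fnn",
                       feature_format: str = "targetfinder",
                       config: Optional[TrainingConfig] = None,
                       seeds: Sequence[int] = (0, 1, 2, 3, 4),
                       max_epochs: int = 60) -> LeakageResult:
    """Train identical models under random and chromosome-held-out splits.

    With element reuse and a planted element-linked (leak) feature the
    expected direction is random > chromosome: the random split rewards
    memorizing elements, the chromosome split cannot.
    """
    if dataset.provenance.duplication_factor <= 1:
        warnings.warn("leakage mechanism absent: dataset has no element "
                      "reuse (duplication_factor <= 1)")
    X = prepare_features(dataset, feature_format)
    rand_aucs, chrom_aucs = [], []
    for s in seeds:
        rand_aucs.append(run_random_split_eval(
            dataset, model_name, feature_format, config, seed=s,
            max_epochs=max_epochs, features=X))
        chrom_aucs.append(run_chromosome_sweep(
            dataset, model_name, feature_format, config, seed=s,
            max_epochs=max_epochs, features=X).weighted_mean)
    comp = paired_t_test(rand_aucs, chrom_aucs) if len(seeds) > 1 else \
        PairedComparison(np.array(rand_aucs) - np.array(chrom_aucs),
                         np.nan, np.nan, 1, degenerate=True)
    return LeakageResult(rand_aucs, chrom_aucs, comp)


def plot_auroc_distributions(summaries: Dict[str, EvalSummary],
                             path: str) -> None:
    """Boxplot of per-chromosome test AUROCs per model, written as SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    names = list(summaries)
    data = [summaries[n].aurocs for n in names]
    fig, ax = plt.subplots(figsize=(1.5 * max(len(names), 3) + 2, 4))
    ax.boxplot(data, tick_labels=names)
    ax.axhline(0.5, color="grey", ls="--", lw=0.8)
    ax.set_ylabel("test AUROC per chromosome")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
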