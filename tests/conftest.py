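"""Shared fixtures: synthetic datasets and the desk-scale experiment setup.

The heavier datasets are session-scoped so the evaluation experiments
(null calibration, leakage demonstration, data-source ordering) reuse one
generation/featurization pass each.
"""

import warnings

import numpy as np
import pytest

import epipred as ep
from epipred.models import TrainingConfig, build_fnn

warnings.filterwarnings("ignore", message=".*single-class.*")
warnings.filterwarnings("ignore", message=".*lacks both.*")


def experiment_fnn(seed: int):
    """FNN sized for the synthetic desk-scale experiments (see
    docs/methods.md)."""
    return build_fnn(input_dim=44, hidden=(128, 64), seed=seed)


@pytest.fixture(scope="session")
def exp_config() -> TrainingConfig:
    return TrainingConfig(batch_size=200, learning_rate=1e-3, conv_l2=0.0)


@pytest.fixture(scope="session")
def fnn_builder():
    return experiment_fnn


@pytest.fixture(scope="session")
def ds_null():
    """No planted signal of any kind."""
    return ep.generate_dataset(ep.SyntheticConfig(
        n_pairs=2000, epi_effect=0.0, seq_motif_rate=0.0, seed=11))


@pytest.fixture(scope="session")
def ds_signal():
    """Planted epigenomic effect, no sequence motif."""
    return ep.generate_dataset(ep.SyntheticConfig(
        n_pairs=2000, epi_effect=2.0, seq_motif_rate=0.0, seed=5))


@pytest.fixture(scope="session")
def ds_leak():
    """No generalizable signal, element reuse x5, strong planted leak."""
    ds = ep.generate_dataset(ep.SyntheticConfig(
        n_pairs=2000, epi_effect=0.0, duplication_factor=5.0, seed=7))
    return ep.plant_leak_feature(ds, strength=3.0)


@pytest.fixture(scope="session")
def X_null(ds_null):
    return (ep.targetfinder_format(ds_null),)


@pytest.fixture(scope="session")
def X_signal(ds_signal):
    return (ep.targetfinder_format(ds_signal),)


@pytest.fixture(scope="session")
def X_leak(ds_leak):
    return (ep.targetfinder_format(ds_leak),)


@pytest.fixture(scope="session")
def small_ds():
    """A small, quick dataset for structural tests (includes chr8/chr9 so
    split plans can be built)."""
    return ep.generate_dataset(ep.SyntheticConfig(
        n_pairs=200, n_chromosomes=9, bp_per_unit=3000, min_distance=4000,
        duplication_factor=2.0, seed=2))


def null_band_3se(dataset, summary) -> float:
    """3x the standard error of the weighted-mean AUROC under the
    Mann-Whitney null, from the realized per-chromosome class counts."""
    labels = dataset.labels
    chroms = dataset.chroms
    ses = []
    for c in summary.per_chrom:
        y = labels[chroms == c]
        ses.append(ep.mann_whitney_null_se(int(y.sum()),
                                           int(len(y) - y.sum())))
    w = summary.weights
    return 3.0 * float(np.sqrt(np.sum(w ** 2 * np.asarray(ses) ** 2)))
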