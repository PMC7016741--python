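"""Train/validation/test split construction.

The leakage-free protocol holds out whole chromosomes: chr8 and chr9 are
always validation; each remaining chromosome serves in turn as the test
set while all others train. Because duplicated or overlapping elements
always live on a single chromosome, no element can span partitions.

``random_split`` implements the conventional uniform random partition of
pairs. It is provided only for the leakage demonstration: with element
reuse it almost surely places shared elements on both sides of the
train/test boundary.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .types import EPPair, SplitPlan, natural_chrom_key

VALIDATION_CHROMS = frozenset({"chr8", "chr9"})


def make_split_plans(chromosomes: Iterable[str]) -> List[SplitPlan]:
    """One SplitPlan per non-validation chromosome, in natural order."""
    chroms = set(chromosomes)
    missing = VALIDATION_CHROMS - chroms
    if missing:
        raise ValueError(f"validation chromosomes missing: {sorted(missing)}")
    test_pool = sorted(chroms - VALIDATION_CHROMS, key=natural_chrom_key)
    if not test_pool:
        raise ValueError("need at least one non-validation chromosome")
    plans = []
    for test in test_pool:
        train = frozenset(chroms - VALIDATION_CHROMS - {test})
        if not train:
            raise ValueError(f"empty training partition for test "
                             f"chromosome {test}")
        plans.append(SplitPlan(validation_chroms=frozenset(VALIDATION_CHROMS),
                               test_chrom=test, train_chroms=train))
    return plans


def assign_pairs(pairs: Sequence[EPPair], plan: SplitPlan
                 ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition pair indices by (enhancer) chromosome into
    (train, validation, test) index arrays."""
    train, val, test = [], [], []
    for i, p in enumerate(pairs):
        c = p.chrom
        if c in plan.train_chroms:
            train.append(i)
        elif c in plan.validation_chroms:
            val.append(i)
        elif c == plan.test_chrom:
            test.append(i)
        else:
            raise ValueError(f"pair {i} on unknown chromosome {c}")
    return (np.array(train, dtype=np.intp), np.array(val, dtype=np.intp),
            np.array(test, dtype=np.intp))


def random_split(pairs: Sequence[EPPair],
                 fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
                 seed: int = 0
                 ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniform random partition of pair indices (the known-biased scheme)."""
    if any(f <= 0 for f in fractions):
        raise ValueError("all fractions must be positive")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(pairs)
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]


def shared_elements_across(pairs: Sequence[EPPair], idx_a: np.ndarray,
                           idx_b: np.ndarray) -> Dict[str, int]:
    """Element identifiers appearing in both index sets (the leakage
    channel); maps id -> number of crossing occurrences."""
    ids_a = {pairs[i].enhancer_id for i in idx_a} | {pairs[i].promoter_id
                                                     for i in idx_a}
    crossing: Dict[str, int] = {}
    for i in idx_b:
        for eid in (pairs[i].enhancer_id, pairs[i].promoter_id):
            if eid in ids_a:
                crossing[eid] = crossing.get(eid, 0) + 1
    return crossing


def plan_to_dict(plan: SplitPlan) -> Dict[str, List[str]]:
    key = natural_chrom_key
    return {"train": sorted(plan.train_chroms, key=key),
            "validation": sorted(plan.validation_chroms, key=key),
            "test": [plan.test_chrom]}
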