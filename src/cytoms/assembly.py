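"""Train/test splitting and class balancing by majority-class partition.

The training protocol here is undersampling-free balancing: the majority
class of the training set is partitioned into ceil(n_majority/n_minority)
near-equal parts, and each part is paired with the *full* minority class.
One classifier is later trained per balanced subset and their predictions
combined by majority vote, so every majority-class record is used exactly
once while every subset is (near-)balanced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SplitSpec:
    """How to divide a cohort table into train and test.

    mode 'by_count' draws exactly the stated number of records per class
    into training (the published bookkeeping: 750 MS + 150 controls in
    training out of 910/199 leaves a 209-record test set). mode
    'by_fraction' takes a class-stratified fraction into training.
    """

    mode: str = "by_count"
    train_ms_count: Optional[int] = None
    train_control_count: Optional[int] = None
    train_fraction: Optional[float] = None
    label_column: str = "status"
    positive_label: str = "MS"
    negative_label: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode == "by_count":
            if self.train_ms_count is None or self.train_control_count is None:
                raise ValueError("by_count mode requires both per-class counts")
            if self.train_ms_count < 0 or self.train_control_count < 0:
                raise ValueError("per-class counts must be non-negative")
        elif self.mode == "by_fraction":
            if self.train_fraction is None or not 0 < self.train_fraction < 1:
                raise ValueError("by_fraction mode requires train_fraction in (0, 1)")
        else:
            raise ValueError(f"unknown split mode {self.mode!r}")


@dataclass
class BalancedBundle:
    """The balanced training subsets plus bookkeeping."""

    subsets: List[pd.DataFrame]
    minority_class: str
    majority_class: str
    label_column: str = "status"

    @property
    def subset_count(self) -> int:
        return len(self.subsets)


def shuffle_and_split(table: pd.DataFrame,
                      spec: SplitSpec) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random split of *table* into (train, test).

    Training membership is drawn uniformly at random per class; train and
    test are disjoint and together reproduce the input exactly.
    """
    labels = table[spec.label_column]
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("split requires records from both classes")

    rng = np.random.default_rng(spec.seed)
    train_parts = []
    test_parts = []
    for cls, sub in table.groupby(spec.label_column, sort=True):
        if spec.mode == "by_count":
            want = (spec.train_ms_count if cls == spec.positive_label
                    else spec.train_control_count)
            if want > len(sub):
                raise ValueError(
                    f"class {cls!r}: requested {want} training records but only "
                    f"{len(sub)} available (short by {want - len(sub)})")
        else:
            want = int(round(spec.train_fraction * len(sub)))
            want = min(max(want, 1), len(sub) - 1)
        idx = rng.permutation(len(sub))
        train_parts.append(sub.iloc[idx[:want]])
        test_parts.append(sub.iloc[idx[want:]])

    train = pd.concat(train_parts).sample(frac=1, random_state=spec.seed + 1)
    test = pd.concat(test_parts).sample(frac=1, random_state=spec.seed + 2)
    if test.empty:
        raise ValueError("split leaves an empty test set")
    return train.reset_index(drop=True), test.reset_index(drop=True)


def near_equal_part_sizes(total: int, parts: int) -> List[int]:
    """Partition sizes differing by at most 1, larger parts first."""
    base, extra = divmod(total, parts)
    return [base + 1] * extra + [base] * (parts - extra)


def balance_by_subsets(train: pd.DataFrame,
                       label_column: str = "status",
                       subset_count: Optional[int] = None,
                       seed: int = 0) -> BalancedBundle:
    """Decompose the training set into balanced subsets.

    The majority class is shuffled (seeded) and partitioned into
    ceil(n_majority/n_minority) near-equal disjoint parts (override via
    *subset_count*); each part is concatenated with the full minority class.
    With n_majority an exact multiple k of n_minority this yields k subsets
    of 2*n_minority rows each.
    """
    counts = train[label_column].value_counts()
    if len(counts) < 2:
        raise ValueError("balancing requires records from both classes")
    if len(counts) > 2:
        raise ValueError(f"expected a binary label, got {list(counts.index)}")

    # sort by (count, label) so equal-sized classes still get two distinct
    # roles deterministically
    ordered = sorted(counts.items(), key=lambda kv: (kv[1], str(kv[0])))
    (minority_class, n_min), (majority_class, n_maj) = ordered

    k = subset_count if subset_count is not None else int(np.ceil(n_maj / n_min))
    if k < 1:
        raise ValueError("subset_count must be >= 1")

    rng = np.random.default_rng(seed)
    majority = train[train[label_column] == majority_class]
    minority = train[train[label_column] == minority_class]
    order = rng.permutation(len(majority))
    sizes = near_equal_part_sizes(len(majority), k)

    subsets = []
    start = 0
    for size in sizes:
        part = majority.iloc[order[start:start + size]]
        start += size
        subsets.append(pd.concat([part, minority]).reset_index(drop=True))
    return BalancedBundle(subsets=subsets, minority_class=minority_class,
                          majority_class=majority_class,
                          label_column=label_column)
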