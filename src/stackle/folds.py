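"""Cross-validation fold assignment.

The stacking procedure keeps every fold model, so the fold partition is part
of the trained model and must be reproducible: the assignment is a pure
function of (n, nfold, seed, stratify_labels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import InputError


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of n training samples into ``nfold`` disjoint folds."""

    fold_of_sample: np.ndarray  # length n, values in 0..nfold-1
    nfold: int
    seed: int

    def __post_init__(self) -> None:
        counts = np.bincount(self.fold_of_sample, minlength=self.nfold)
        if counts.min() == 0:
            raise InputError("every fold must be non-empty")

    @property
    def n(self) -> int:
        return len(self.fold_of_sample)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample != fold)

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.fold_of_sample, minlength=self.nfold)


def assign_folds(
    n: int,
    nfold: int,
    seed: int,
    stratify_labels: Optional[Sequence] = None,
) -> FoldAssignment:
    """Randomly partition ``n`` samples into ``nfold`` folds of near-equal size.

    With ``stratify_labels`` the split preserves label frequencies per fold
    (classification); default is an unstratified uniform random partition.
    """
    if nfold < 2:
        raise InputError(f"nfold must be >= 2, got {nfold}")
    if nfold > n:
        raise InputError(f"nfold ({nfold}) cannot exceed the sample count ({n})")
    fold_of_sample = np.empty(n, dtype=np.int64)
    if stratify_labels is None:
        splitter = KFold(n_splits=nfold, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros((n, 1)))
    else:
        labels = np.asarray(stratify_labels)
        if len(labels) != n:
            raise InputError("stratify_labels length must equal n")
        splitter = StratifiedKFold(n_splits=nfold, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros((n, 1)), labels)
    for fold, (_, test_idx) in enumerate(splits):
        fold_of_sample[test_idx] = fold
    return FoldAssignment(fold_of_sample=fold_of_sample, nfold=nfold, seed=seed)
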