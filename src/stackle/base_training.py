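"""Fold-wise base-learner training and out-of-fold meta-feature construction.

For each of the ``nfold`` folds and each of the L base learners, a model is
fitted on the samples *outside* the fold; its predictions on the held-out fold
fill that fold's rows of the learner's meta-feature column.  Every training
sample is therefore predicted exactly once per learner, by a model that never
saw it — the no-leakage property the meta-learner depends on.

The ``nfold × L`` fitted models are all kept: at prediction time each
learner's fold models are averaged (regression) or majority-voted
(classification) rather than refitting on the full data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .exceptions import InputError
from .folds import FoldAssignment, assign_folds
from .registry import CLASSIFICATION, REGRESSION, BaseLearnerConfig, get_adapter
from .seeding import NS_BASE, derive_seed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitFailure:
    """Marker recorded for a (fold, learner) cell whose fit raised."""

    fold: int
    learner_index: int
    message: str


@dataclass
class BaseModelMatrix:
    """The ``nfold × L`` grid of fitted base models (or failure markers)."""

    models: list[list[Any]]  # [fold][learner] -> fitted state or FitFailure
    configs: list[BaseLearnerConfig]
    folds: FoldAssignment
    task: str
    seed: int

    @property
    def nfold(self) -> int:
        return self.folds.nfold

    @property
    def n_learners(self) -> int:
        return len(self.configs)

    def cell(self, fold: int, learner_index: int) -> Any:
        return self.models[fold][learner_index]

    def failures(self) -> list[FitFailure]:
        return [m for row in self.models for m in row if isinstance(m, FitFailure)]

    def failed_learners(self) -> list[int]:
        """Learners for which every fold model failed."""
        out = []
        for cfg in self.configs:
            if all(isinstance(self.models[f][cfg.learner_index], FitFailure)
                   for f in range(self.nfold)):
                out.append(cfg.learner_index)
        return out

    def n_fitted(self) -> int:
        return sum(not isinstance(m, FitFailure) for row in self.models for m in row)


@dataclass
class MetaFeatureTable:
    """The n × L out-of-fold prediction table used as the meta-learner design.

    Columns are labelled by ``learner_index``; rows follow the input sample
    order of X/Y.  For classification the cells hold predicted class labels,
    not probabilities.
    """

    values: pd.DataFrame
    fold_of_row: np.ndarray
    learner_columns: list[BaseLearnerConfig] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def learner_indices(self) -> list[int]:
        return list(self.values.columns)


def _validate_xy(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X)
    if X.ndim != 2:
        raise InputError(f"X must be 2-dimensional, got shape {X.shape}")
    if not np.isfinite(X.astype(float, copy=False)).all():
        raise InputError("X contains missing or non-finite values")
    Y = np.asarray(Y)
    if Y.ndim != 1:
        Y = Y.reshape(-1)
    if len(Y) != len(X):
        raise InputError(f"X has {len(X)} rows but Y has {len(Y)} values")
    if Y.dtype.kind in "fiu" and not np.isfinite(Y.astype(float)).all():
        raise InputError("Y contains missing or non-finite values")
    return X, Y


def _fit_cell(X, Y, folds, cfg, task, fold, seed):
    """Fit one (fold, learner) cell and predict its held-out fold."""
    adapter = get_adapter(cfg.method_name)
    cell_seed = derive_seed(seed, NS_BASE, fold, cfg.learner_index)
    train_idx = folds.train_indices(fold)
    test_idx = folds.test_indices(fold)
    try:
        fitted = adapter.fit(X[train_idx], Y[train_idx], cfg.hyperparameters, task, cell_seed)
        oof = adapter.predict(fitted, X[test_idx])
        return fitted, oof
    except Exception as exc:  # noqa: BLE001 - continue-and-report policy
        return FitFailure(fold, cfg.learner_index, f"{type(exc).__name__}: {exc}"), None


def train_base_models(
    X: np.ndarray,
    Y: np.ndarray,
    folds: FoldAssignment,
    configs: Sequence[BaseLearnerConfig],
    task: str = REGRESSION,
    cores: int = 1,
    seed: int = 0,
) -> tuple[BaseModelMatrix, MetaFeatureTable]:
    """Train every base learner on every training split and collect
    out-of-fold predictions.

    The ``nfold × L`` fits are independent; with ``cores > 1`` they run
    concurrently and, because each cell derives its own seed from
    ``(seed, fold, learner)``, results are identical to sequential execution.

    A cell whose fit raises is recorded as a :class:`FitFailure` and training
    continues; a learner whose every fold fails is dropped from the
    meta-feature table with a warning.
    """
    X, Y = _validate_xy(X, Y)
    if cores < 1:
        raise InputError(f"cores must be >= 1, got {cores}")
    configs = list(configs)
    if not configs:
        raise InputError("at least one base learner is required")
    if task not in (REGRESSION, CLASSIFICATION):
        raise InputError(f"unknown task '{task}'")

    cells = [(f, cfg) for f in range(folds.nfold) for cfg in configs]
    results = Parallel(n_jobs=cores)(
        delayed(_fit_cell)(X, Y, folds, cfg, task, f, seed) for f, cfg in cells
    )

    models: list[list[Any]] = [[None] * len(configs) for _ in range(folds.nfold)]
    if task == CLASSIFICATION:
        oof = np.full((len(X), len(configs)), None, dtype=object)
    else:
        oof = np.full((len(X), len(configs)), np.nan)
    for (f, cfg), (state, preds) in zip(cells, results):
        models[f][cfg.learner_index] = state
        if preds is not None:
            oof[folds.test_indices(f), cfg.learner_index] = preds

    base = BaseModelMatrix(models=models, configs=configs, folds=folds, task=task, seed=seed)
    for failure in base.failures():
        logger.warning(
            "base model fit failed (fold=%d, learner=%d): %s",
            failure.fold, failure.learner_index, failure.message,
        )

    keep = [c.learner_index for c in configs if c.learner_index not in set(base.failed_learners())]
    dropped = sorted(set(range(len(configs))) - set(keep))
    if dropped:
        warnings.warn(
            f"learners {dropped} failed in every fold and were dropped from the "
            "meta-feature table",
            RuntimeWarning,
            stacklevel=2,
        )
    values = pd.DataFrame(oof, columns=range(len(configs)))[keep]
    # partially failed learners may have missing out-of-fold rows; those rows
    # cannot feed the meta-learner, so refuse them explicitly
    if task == REGRESSION:
        incomplete = values.columns[values.isna().any()].tolist()
    else:
        incomplete = values.columns[values.isnull().any()].tolist()
    if incomplete:
        warnings.warn(
            f"learners {incomplete} have incomplete out-of-fold predictions "
            "(some folds failed) and were dropped from the meta-feature table",
            RuntimeWarning,
            stacklevel=2,
        )
        values = values.drop(columns=incomplete)
    if values.shape[1] == 0:
        raise InputError("every base learner failed; cannot build meta-features")

    meta = MetaFeatureTable(
        values=values,
        fold_of_row=folds.fold_of_sample.copy(),
        learner_columns=[configs[i] for i in values.columns],
    )
    logger.info(
        "trained base models: nfold=%d, L=%d, fitted=%d, failed=%d, seed=%d",
        folds.nfold, len(configs), base.n_fitted(), len(base.failures()), seed,
    )
    return base, meta


__all__ = [
    "FitFailure",
    "BaseModelMatrix",
    "MetaFeatureTable",
    "train_base_models",
    "assign_folds",
]
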