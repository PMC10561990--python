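"""Meta-learner training on out-of-fold base predictions.

Two modes exist.  Pooled (the default): one meta-model is fitted on all n
out-of-fold rows at once.  Per-fold: one meta-model per fold, each fitted on
that fold's rows only, with their outputs averaged (regression) or
majority-voted (classification) at prediction time.

For regression the meta design is simply the selected columns of the
out-of-fold table.  For classification the cells are class labels; each
selected column is expanded into indicator variables with the first (sorted)
observed category dropped as the reference level.  The category set of each
column is frozen at training time; categories never seen in training map to
the all-zero encoding at prediction, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .base_training import MetaFeatureTable
from .exceptions import InputError
from .registry import (
    CLASSIFICATION,
    REGRESSION,
    BaseLearnerConfig,
    MethodSpec,
    get_adapter,
)
from .seeding import NS_META, derive_seed


@dataclass(frozen=True)
class MetaDesignEncoder:
    """Frozen mapping from selected meta-feature columns to the design matrix."""

    task: str
    which_to_use: tuple[int, ...]
    categories: Optional[dict[int, tuple]] = None  # per column, sorted label set

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.which_to_use if c not in table.columns]
        if missing:
            raise InputError(f"meta-feature columns {missing} are unavailable")
        sub = table[list(self.which_to_use)]
        if self.task == REGRESSION:
            return sub.astype(float)
        blocks = []
        for col in self.which_to_use:
            cats = self.categories[col]
            vals = sub[col].to_numpy()
            unseen = set(np.unique(vals.astype(object))) - set(cats)
            if unseen:
                warnings.warn(
                    f"column {col}: categories {sorted(map(str, unseen))} unseen at "
                    "training time map to the all-zero encoding",
                    RuntimeWarning,
                    stacklevel=3,
                )
            # reference level = first sorted category, dropped
            block = pd.DataFrame(
                {f"c{col}={cat}": (vals == cat).astype(float) for cat in cats[1:]},
                index=sub.index,
            )
            blocks.append(block)
        return pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=sub.index)


def fit_meta_design_encoder(
    meta_features: MetaFeatureTable,
    which_to_use: Sequence[int],
    task: str,
) -> MetaDesignEncoder:
    which = tuple(int(i) for i in which_to_use)
    if not which:
        raise InputError("which_to_use must name at least one base learner")
    if len(set(which)) != len(which):
        raise InputError("which_to_use contains duplicate learner indices")
    available = set(meta_features.values.columns)
    unknown = [i for i in which if i not in available]
    if unknown:
        raise InputError(
            f"which_to_use names learners {unknown} absent from the meta-feature table"
        )
    categories = None
    if task == CLASSIFICATION:
        categories = {
            col: tuple(sorted(np.unique(meta_features.values[col].to_numpy().astype(object)),
                              key=str))
            for col in which
        }
    return MetaDesignEncoder(task=task, which_to_use=which, categories=categories)


def build_meta_design(
    meta_features: MetaFeatureTable,
    which_to_use: Optional[Sequence[int]] = None,
    task: str = REGRESSION,
) -> pd.DataFrame:
    """Column-subset (and, for classification, indicator-encode) the
    out-of-fold table into the meta-learner's design matrix."""
    if which_to_use is None:
        which_to_use = meta_features.learner_indices
    encoder = fit_meta_design_encoder(meta_features, which_to_use, task)
    return encoder.transform(meta_features.values)


def _as_meta_config(meta_method: Union[str, MethodSpec, BaseLearnerConfig]) -> BaseLearnerConfig:
    if isinstance(meta_method, BaseLearnerConfig):
        return meta_method
    if isinstance(meta_method, str):
        meta_method = MethodSpec(meta_method)
    elif isinstance(meta_method, tuple) and len(meta_method) == 2:
        meta_method = MethodSpec(meta_method[0], meta_method[1])
    if isinstance(meta_method, MethodSpec):
        rows = meta_method.rows()
        if len(rows) != 1:
            raise InputError(
                "the meta-learner takes exactly one hyperparameter setting, "
                f"got {len(rows)} rows"
            )
        return BaseLearnerConfig(meta_method.method_name, rows[0], learner_index=0)
    raise InputError(f"cannot interpret meta-learner spec {meta_method!r}")


@dataclass
class MetaModel:
    """The fitted meta-learner(s): one state pooled, or one per fold."""

    fitted_states: list[Any]
    meta_config: BaseLearnerConfig
    train_each_fold: bool
    which_to_use: tuple[int, ...]
    encoder: MetaDesignEncoder
    task: str
    seed: int

    @property
    def nfits(self) -> int:
        return len(self.fitted_states)


def train_meta_model(
    meta_features: MetaFeatureTable,
    Y: np.ndarray,
    meta_method: Union[str, MethodSpec, BaseLearnerConfig],
    train_each_fold: bool = False,
    which_to_use: Optional[Sequence[int]] = None,
    task: str = REGRESSION,
    seed: int = 0,
) -> MetaModel:
    """Fit the meta-learner on the out-of-fold predictions.

    Pooled mode (``train_each_fold=False``, the default) fits once on all n
    rows.  Per-fold mode fits ``nfold`` models, model f using exactly the rows
    of fold f and their Y values.
    """
    Y = np.asarray(Y).reshape(-1)
    if len(Y) != meta_features.n:
        raise InputError(
            f"meta-feature table has {meta_features.n} rows but Y has {len(Y)}"
        )
    if which_to_use is None:
        which_to_use = meta_features.learner_indices
    cfg = _as_meta_config(meta_method)
    adapter = get_adapter(cfg.method_name)
    encoder = fit_meta_design_encoder(meta_features, which_to_use, task)
    design = encoder.transform(meta_features.values)

    states: list[Any] = []
    if not train_each_fold:
        states.append(
            adapter.fit(design.to_numpy(), Y, cfg.hyperparameters, task,
                        derive_seed(seed, NS_META, 0))
        )
    else:
        nfold = int(meta_features.fold_of_row.max()) + 1
        for f in range(nfold):
            rows = np.flatnonzero(meta_features.fold_of_row == f)
            try:
                states.append(
                    adapter.fit(design.to_numpy()[rows], Y[rows], cfg.hyperparameters,
                                task, derive_seed(seed, NS_META, f))
                )
            except Exception as exc:
                raise InputError(
                    f"meta-learner failed on fold {f} ({len(rows)} rows): {exc}"
                ) from exc
    return MetaModel(
        fitted_states=states,
        meta_config=cfg,
        train_each_fold=train_each_fold,
        which_to_use=encoder.which_to_use,
        encoder=encoder,
        task=task,
        seed=seed,
    )
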