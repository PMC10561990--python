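"""Scikit-learn style stacking estimators.

:class:`StackingRegressor` and :class:`StackingClassifier` wrap the whole
pipeline — fold assignment, fold-wise base training, out-of-fold meta-feature
construction, meta training and fold-model-averaged prediction — behind the
standard ``fit`` / ``predict`` / ``get_params`` contract, so they compose with
sklearn pipelines, ``clone`` and model selection.

``base_learners`` accepts a list of :class:`~stackle.registry.MethodSpec`, or
``(method_name, table)`` pairs, or ``{"method": ..., "rows"/"grid": ...}``
dicts; one base learner is created per hyperparameter row.  ``meta_learner``
accepts a method name, a :class:`MethodSpec` with one row, or a
``(method_name, mapping)`` pair.

The thin functional API (:func:`train_stacking`, :func:`predict_from_model`)
delegates to these classes.
"""

from __future__ import annotations

from typing import Any, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from .base_training import train_base_models
from .exceptions import ConfigurationError, InputError
from .folds import assign_folds
from .meta_training import train_meta_model
from .prediction import StackedModel, predict_stacking
from .registry import (
    CLASSIFICATION,
    REGRESSION,
    BaseLearnerConfig,
    MethodSpec,
    expand_base_learners,
)

SpecLike = Union[MethodSpec, tuple, Mapping[str, Any]]


def as_method_spec(spec: SpecLike) -> MethodSpec:
    """Normalize the accepted spec shapes to a MethodSpec."""
    if isinstance(spec, MethodSpec):
        return spec
    if isinstance(spec, tuple) and len(spec) == 2:
        return MethodSpec(spec[0], spec[1])
    if isinstance(spec, Mapping):
        d = dict(spec)
        if "method" not in d:
            raise ConfigurationError(f"base-learner spec {spec!r} lacks a 'method' key")
        name = d.pop("method")
        if "rows" in d:
            return MethodSpec(name, d["rows"])
        if "grid" in d:
            from .registry import cartesian_grid

            return MethodSpec(name, cartesian_grid(d["grid"]))
        return MethodSpec(name, [d] if d else [{}])
    if isinstance(spec, str):
        return MethodSpec(spec)
    raise ConfigurationError(f"cannot interpret base-learner spec {spec!r}")


def as_method_specs(specs: Sequence[SpecLike]) -> list[MethodSpec]:
    return [as_method_spec(s) for s in specs]


class _BaseStacking(BaseEstimator):
    _task: str = REGRESSION

    def __init__(
        self,
        base_learners: Optional[Sequence[SpecLike]] = None,
        meta_learner: SpecLike = "elastic_net",
        n_folds: int = 5,
        train_each_fold: bool = False,
        which_to_use: Optional[Sequence[int]] = None,
        stratify: bool = False,
        n_jobs: int = 1,
        random_state: int = 0,
    ):
        self.base_learners = base_learners
        self.meta_learner = meta_learner
        self.n_folds = n_folds
        self.train_each_fold = train_each_fold
        self.which_to_use = which_to_use
        self.stratify = stratify
        self.n_jobs = n_jobs
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def _resolve_configs(self) -> list[BaseLearnerConfig]:
        if not self.base_learners:
            raise ConfigurationError("base_learners must name at least one method")
        return expand_base_learners(as_method_specs(self.base_learners))

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            feature_names = [str(c) for c in X.columns]
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            if Xv.ndim != 2:
                raise InputError(f"X must be 2-dimensional, got shape {Xv.shape}")
            feature_names = [f"x{j}" for j in range(Xv.shape[1])]
        y = np.asarray(y).reshape(-1)
        if self._task == CLASSIFICATION:
            self.classes_ = np.unique(y.astype(object))

        configs = self._resolve_configs()
        stratify_labels = y if (self._task == CLASSIFICATION and self.stratify) else None
        folds = assign_folds(len(Xv), self.n_folds, seed=int(self.random_state),
                             stratify_labels=stratify_labels)
        base, meta_features = train_base_models(
            Xv, y, folds, configs, task=self._task,
            cores=int(self.n_jobs), seed=int(self.random_state),
        )
        meta = train_meta_model(
            meta_features, y, as_method_spec(self.meta_learner),
            train_each_fold=bool(self.train_each_fold),
            which_to_use=self.which_to_use,
            task=self._task, seed=int(self.random_state),
        )
        self.model_ = StackedModel(base=base, meta=meta, task=self._task,
                                   feature_names=feature_names)
        self.meta_features_ = meta_features
        self.folds_ = folds
        self.n_features_in_ = Xv.shape[1]
        self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        self.n_base_learners_ = len(configs)
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise InputError("this stacking model is not fitted yet; call fit first")
        return predict_stacking(X, self.model_)

    def aggregated_meta_features(self, X) -> pd.DataFrame:
        """Per-learner aggregated predictions for new samples (Step 7 output)."""
        from .prediction import aggregate_per_learner, predict_base

        raw = predict_base(X, self.model_.base, self.model_.feature_names)
        return aggregate_per_learner(raw, self._task)


class StackingRegressor(RegressorMixin, _BaseStacking):
    """Stacked generalization for continuous responses.

    Fold models are never refit on the full data: at prediction time each base
    learner's ``n_folds`` fold-model outputs are averaged before the
    meta-model produces the final value.
    """

    _task = REGRESSION


class StackingClassifier(ClassifierMixin, _BaseStacking):
    """Stacked generalization for categorical responses.

    Base-learner meta-features are predicted class labels; per-learner
    aggregation takes the modal category across fold models, and per-fold
    meta-models are combined by majority vote.
    """

    _task = CLASSIFICATION


# -- functional API ---------------------------------------------------------

def train_stacking(
    X,
    Y,
    n_folds: int = 5,
    base_learners: Optional[Sequence[SpecLike]] = None,
    meta_learner: SpecLike = "elastic_net",
    train_each_fold: bool = False,
    which_to_use: Optional[Sequence[int]] = None,
    task: str = REGRESSION,
    cores: int = 1,
    seed: int = 0,
) -> StackedModel:
    """One-call training of the full stack; returns the trained model."""
    cls = StackingRegressor if task == REGRESSION else StackingClassifier
    est = cls(
        base_learners=base_learners,
        meta_learner=meta_learner,
        n_folds=n_folds,
        train_each_fold=train_each_fold,
        which_to_use=which_to_use,
        n_jobs=cores,
        random_state=seed,
    )
    est.fit(X, Y)
    return est.model_


def predict_from_model(newX, model: StackedModel) -> np.ndarray:
    """One-call prediction from a trained stacked model."""
    return predict_stacking(newX, model)
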