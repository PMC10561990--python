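"""Prediction through a trained stack, and model persistence.

New samples are fed to all ``nfold × L`` fold models; the raw predictions are
then aggregated per base learner (arithmetic mean for regression, modal
category for classification) and the aggregated values are fed to the
meta-model(s) as explanatory variables.  In per-fold mode the outputs of the
``nfold`` meta-models are averaged (regression) or majority-voted
(classification).

Modal-category ties are broken by the lexicographically smallest label, so
prediction is deterministic.

Feature alignment is by column NAME (order-normalized) when the new data
carries names; silent positional misalignment is the classic stacking bug and
is rejected loudly.
"""

from __future__ import annotations

import json
import pickle
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Union

import numpy as np
import pandas as pd

from .base_training import BaseModelMatrix, FitFailure
from .exceptions import InputError, PredictionError
from .meta_training import MetaModel
from .registry import CLASSIFICATION, REGRESSION, get_adapter


@dataclass
class StackedModel:
    """Everything needed for prediction: fold models, meta-model(s), metadata."""

    base: BaseModelMatrix
    meta: MetaModel
    task: str
    feature_names: list[str]

    def __post_init__(self) -> None:
        if not self.feature_names:
            raise InputError("feature_names must be non-empty")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise InputError("feature_names contains duplicates")
        valid = {c.learner_index for c in self.base.configs}
        if not set(self.meta.which_to_use) <= valid:
            raise InputError("meta.which_to_use names learners absent from the base grid")


def _align_features(newX, feature_names: list[str]) -> np.ndarray:
    """Normalize column order by name; reject mismatched column sets."""
    if isinstance(newX, pd.DataFrame):
        cols = [str(c) for c in newX.columns]
        missing = sorted(set(feature_names) - set(cols))
        extra = sorted(set(cols) - set(feature_names))
        if missing or extra:
            raise InputError(
                f"feature columns do not match the training data: "
                f"missing={missing}, extra={extra}"
            )
        return newX[feature_names].to_numpy(dtype=float)
    X = np.asarray(newX, dtype=float)
    if X.ndim == 1:
        X = X.reshape(0, len(feature_names)) if X.size == 0 else X.reshape(1, -1)
    if X.shape[1] != len(feature_names):
        raise InputError(
            f"newX has {X.shape[1]} columns but the model was trained on "
            f"{len(feature_names)} features"
        )
    return X


def predict_base(newX, base: BaseModelMatrix,
                 feature_names: list[str] | None = None) -> pd.DataFrame:
    """Feed new samples to all fold models.

    Returns an m × (nfold·L) table with a (learner, fold) column MultiIndex;
    failed cells contribute no column.
    """
    if feature_names is not None:
        X = _align_features(newX, feature_names)
    else:
        X = np.asarray(newX, dtype=float)
        if X.ndim != 2:
            raise InputError(f"newX must be 2-dimensional, got shape {X.shape}")
    columns: dict[tuple[int, int], np.ndarray] = {}
    for cfg in base.configs:
        adapter = get_adapter(cfg.method_name)
        for f in range(base.nfold):
            state = base.cell(f, cfg.learner_index)
            if isinstance(state, FitFailure):
                continue
            # keep the column structure even for zero-row input
            columns[(cfg.learner_index, f)] = (
                np.empty(0) if len(X) == 0 else adapter.predict(state, X)
            )
    raw = pd.DataFrame(columns, index=range(len(X)))
    raw.columns = pd.MultiIndex.from_tuples(raw.columns, names=["learner", "fold"])
    return raw


def _modal_label(values: np.ndarray):
    """Most frequent label; ties broken by lexicographically smallest."""
    labels, counts = np.unique(values.astype(object), return_counts=True)
    order = sorted(range(len(labels)), key=lambda i: (-counts[i], str(labels[i])))
    return labels[order[0]]


def aggregate_per_learner(raw: pd.DataFrame, task: str = REGRESSION) -> pd.DataFrame:
    """Collapse the (learner, fold) raw table to one column per learner.

    Regression: arithmetic mean over the learner's fold-model predictions
    (failed cells simply absent).  Classification: modal predicted category.
    """
    learners = sorted({lrn for lrn, _ in raw.columns})
    out: dict[int, np.ndarray] = {}
    for lrn in learners:
        block = raw[lrn]
        if task == REGRESSION:
            out[lrn] = block.to_numpy(dtype=float).mean(axis=1)
        else:
            vals = block.to_numpy()
            out[lrn] = np.array([_modal_label(row) for row in vals], dtype=object) \
                if len(vals) else np.array([], dtype=object)
    return pd.DataFrame(out, index=raw.index, columns=learners)


def predict_stacking(newX, model: StackedModel) -> np.ndarray:
    """Full prediction pipeline: base models -> per-learner aggregation ->
    meta design -> meta-model(s) -> final prediction vector."""
    raw = predict_base(newX, model.base, model.feature_names)
    aggregated = aggregate_per_learner(raw, model.task)
    missing = set(model.meta.which_to_use) - set(aggregated.columns)
    if missing:
        raise PredictionError(
            f"base learners {sorted(missing)} required by the meta-model produced "
            "no predictions (all fold models failed)"
        )
    design = model.meta.encoder.transform(aggregated)
    adapter = get_adapter(model.meta.meta_config.method_name)
    outputs = [adapter.predict(state, design.to_numpy())
               for state in model.meta.fitted_states]
    if len(outputs) == 1:
        return outputs[0]
    stackd = np.vstack(outputs)
    if model.task == REGRESSION:
        return stackd.astype(float).mean(axis=0)
    return np.array([_modal_label(stackd[:, j]) for j in range(stackd.shape[1])],
                    dtype=object)


# ---------------------------------------------------------------------------
# Persistence: a single zip archive with a human-readable JSON manifest next
# to the pickled fitted states, so archives stay auditable.
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: StackedModel, path: Union[str, Path]) -> None:
    import sklearn

    from . import __version__

    manifest = {
        "format_version": _FORMAT_VERSION,
        "stackle_version": __version__,
        "numpy_version": np.__version__,
        "sklearn_version": sklearn.__version__,
        "task": model.task,
        "nfold": model.base.nfold,
        "n_learners": model.base.n_learners,
        "seed": model.base.seed,
        "feature_names": model.feature_names,
        "train_each_fold": model.meta.train_each_fold,
        "which_to_use": list(model.meta.which_to_use),
        "meta_method": model.meta.meta_config.method_name,
        "base_learners": [
            {"index": c.learner_index, "method": c.method_name,
             "hyperparameters": {k: repr(v) for k, v in c.hyperparameters.items()}}
            for c in model.base.configs
        ],
        "failed_cells": [
            {"fold": fl.fold, "learner": fl.learner_index, "message": fl.message}
            for fl in model.base.failures()
        ],
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2))
        zf.writestr("model.pkl", pickle.dumps(model, protocol=pickle.HIGHEST_PROTOCOL))


def load_model(path: Union[str, Path]) -> StackedModel:
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        if manifest.get("format_version") != _FORMAT_VERSION:
            raise InputError(
                f"unsupported model archive version {manifest.get('format_version')}"
            )
        model = pickle.loads(zf.read("model.pkl"))
    if not isinstance(model, StackedModel):
        raise InputError("archive does not contain a stacked model")
    return model


def read_manifest(path: Union[str, Path]) -> dict:
    with zipfile.ZipFile(path) as zf:
        return json.loads(zf.read("manifest.json"))
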