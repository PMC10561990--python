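"""Delimited-matrix I/O and run-configuration parsing.

CSV dialect: comma separator, ``.`` decimal, mandatory header row, UTF-8.
When the first column is non-numeric it is treated as the sample identifier.
Missing cells are rejected with their (row, column) coordinates — stacking has
no missing-data path, so failures must be loud and located.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .estimators import as_method_spec, as_method_specs
from .exceptions import ConfigurationError, InputError
from .registry import CLASSIFICATION, REGRESSION, MethodSpec, get_adapter


def _check_header(path: Path) -> None:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise InputError(f"{path}: duplicate column name '{name}' in header")
        seen.add(name)


def read_matrix(path: Union[str, Path], numeric: bool = True
                ) -> tuple[pd.DataFrame, Optional[list[str]]]:
    """Read a CSV matrix; returns (frame, sample identifiers or None).

    The frame's columns are the header names; values are float64 when
    ``numeric`` (X and regression Y), else left as categories (classification
    Y).  Raises :class:`InputError` with coordinates on ragged rows, missing
    cells or non-numeric values.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    _check_header(path)
    try:
        df = pd.read_csv(path, header=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise InputError(f"{path}: malformed CSV ({exc})") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise InputError(f"{path}: empty matrix")
    ids: Optional[list[str]] = None
    first = df.columns[0]
    # a lone column is always data, never an identifier column
    if df.shape[1] > 1 and df[first].dtype == object and not _all_numeric(df[first]):
        ids = df[first].astype(str).tolist()
        df = df.drop(columns=[first])
    na = df.isna()
    if na.any().any():
        r, c = np.argwhere(na.to_numpy())[0]
        raise InputError(
            f"{path}: missing value at row {int(r) + 1}, column '{df.columns[c]}'"
        )
    if numeric:
        for col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                bad = df[col].map(lambda v: not _is_number(v))
                r = int(np.argmax(bad.to_numpy()))
                raise InputError(
                    f"{path}: non-numeric cell at row {r + 1}, column '{col}'"
                ) from None
        df = df.astype(float)
    return df, ids


def _is_number(v: Any) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def _all_numeric(s: pd.Series) -> bool:
    return bool(s.map(_is_number).all())


def write_matrix(frame: pd.DataFrame, path: Union[str, Path],
                 ids: Optional[Sequence[str]] = None) -> None:
    """Write a matrix as CSV at full float precision (lossless round trip)."""
    out = frame.copy()
    if ids is not None:
        out.insert(0, "id", list(ids))
    # repr-precision floats round-trip bit-exactly through read_matrix
    out.to_csv(path, index=False, float_format=None)


def read_vector(path: Union[str, Path], numeric: bool = True
                ) -> tuple[np.ndarray, Optional[list[str]]]:
    """Read a response vector from a single-column (or id+value) CSV."""
    df, ids = read_matrix(path, numeric=numeric)
    if df.shape[1] != 1:
        raise InputError(
            f"{path}: expected a single response column, found {df.shape[1]}"
        )
    values = df.iloc[:, 0].to_numpy()
    return (values if numeric else values.astype(object)), ids


# ---------------------------------------------------------------------------
# Run configuration (YAML)
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "base_learners", "meta_learner", "nfold", "train_each_fold",
    "which_to_use", "seed", "cores", "task", "stratify",
}


@dataclass
class RunConfig:
    """Fully defaulted, validated training configuration."""

    base_learners: list[MethodSpec]
    meta_learner: MethodSpec
    nfold: int = 5
    train_each_fold: bool = False
    which_to_use: Optional[list[int]] = None
    seed: int = 0
    cores: int = 1
    task: str = REGRESSION
    stratify: bool = False


def validate_config(raw: Union[str, Mapping[str, Any]]) -> RunConfig:
    """Parse and validate a YAML (or mapping) run configuration.

    Applies defaults (nfold=5, train_each_fold=false, which_to_use=all) and
    fails with the offending key named.
    """
    if isinstance(raw, str):
        try:
            data = yaml.safe_load(raw)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"config is not valid YAML: {exc}") from exc
    else:
        data = dict(raw)
    if not isinstance(data, Mapping):
        raise ConfigurationError("config must be a mapping of settings")
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "base_learners" not in data or not data["base_learners"]:
        raise ConfigurationError("config key 'base_learners' is required and non-empty")
    if "meta_learner" not in data:
        raise ConfigurationError("config key 'meta_learner' is required")
    try:
        base = as_method_specs(data["base_learners"])
    except ConfigurationError as exc:
        raise ConfigurationError(f"base_learners: {exc}") from exc
    try:
        meta = as_method_spec(data["meta_learner"])
    except ConfigurationError as exc:
        raise ConfigurationError(f"meta_learner: {exc}") from exc
    task = data.get("task", REGRESSION)
    if task not in (REGRESSION, CLASSIFICATION):
        raise ConfigurationError(f"task: must be 'regression' or 'classification', got {task!r}")
    for spec in base:
        adapter = get_adapter(spec.method_name)  # raises for unknown methods
        if not adapter.supports(task):
            raise ConfigurationError(
                f"base_learners: method '{spec.method_name}' does not support task '{task}'"
            )
    get_adapter(meta.method_name)
    if meta.n_settings != 1:
        raise ConfigurationError("meta_learner: exactly one hyperparameter row is allowed")
    nfold = int(data.get("nfold", 5))
    if nfold < 2:
        raise ConfigurationError(f"nfold: must be >= 2, got {nfold}")
    cores = int(data.get("cores", 1))
    if cores < 1:
        raise ConfigurationError(f"cores: must be >= 1, got {cores}")
    which = data.get("which_to_use")
    if which is not None:
        which = [int(i) for i in which]
        total = sum(s.n_settings for s in base)
        bad = [i for i in which if i < 0 or i >= total]
        if bad:
            raise ConfigurationError(
                f"which_to_use: indices {bad} out of range for {total} base learners"
            )
        if len(set(which)) != len(which):
            raise ConfigurationError("which_to_use: duplicate indices")
    return RunConfig(
        base_learners=base,
        meta_learner=meta,
        nfold=nfold,
        train_each_fold=bool(data.get("train_each_fold", False)),
        which_to_use=which,
        seed=int(data.get("seed", 0)),
        cores=cores,
        task=task,
        stratify=bool(data.get("stratify", False)),
    )


def load_config(path: Union[str, Path]) -> RunConfig:
    return validate_config(Path(path).read_text(encoding="utf-8"))
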