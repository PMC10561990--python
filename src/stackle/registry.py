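"""Base-learner registry: method specs, grid expansion and estimator adapters.

A *base learner* is one supervised method together with one complete
hyperparameter setting.  A method supplied with a G-row hyperparameter table
therefore contributes G base learners to the ensemble.  Each row of the table
is one complete setting; :func:`cartesian_grid` is the explicit helper that
builds the full combination table from per-parameter value lists.

Adapters wrap mainstream scikit-learn estimators behind a uniform
build/fit/predict contract.  Hyperparameter names are passed through to the
underlying estimator verbatim (``n_estimators``, ``alpha``, ``C``, ...), so the
registry stays auditable: what you write in a config is what the estimator
receives.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import ElasticNet, LinearRegression, LogisticRegression
from sklearn.svm import SVC, SVR

from .exceptions import ConfigurationError

REGRESSION = "regression"
CLASSIFICATION = "classification"
TASKS = (REGRESSION, CLASSIFICATION)


def _as_table(table: Any) -> pd.DataFrame:
    """Coerce a hyperparameter table to a DataFrame and validate it."""
    if isinstance(table, pd.DataFrame):
        df = table.reset_index(drop=True)
    elif isinstance(table, Mapping):
        # single row given as a plain mapping
        df = pd.DataFrame([dict(table)])
    else:
        df = pd.DataFrame(list(table))
    if df.shape[0] < 1:
        raise ConfigurationError("hyperparameter table must have at least one row")
    if df.isna().any().any():
        raise ConfigurationError(
            "hyperparameter table has missing cells; all rows must name the same parameters"
        )
    if df.shape[1] > 0 and df.duplicated().any():
        dup = df.index[df.duplicated()].tolist()
        raise ConfigurationError(f"hyperparameter table has duplicate rows at positions {dup}")
    return df


@dataclass(frozen=True)
class MethodSpec:
    """One method name plus a table of hyperparameter settings (one per row)."""

    method_name: str
    hyperparameter_table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame([{}]))

    def __post_init__(self) -> None:
        object.__setattr__(self, "hyperparameter_table", _as_table(self.hyperparameter_table))

    @property
    def n_settings(self) -> int:
        return len(self.hyperparameter_table)

    def rows(self) -> list[dict[str, Any]]:
        df = self.hyperparameter_table
        # index per column (not df.iloc[i]) so mixed int/float rows keep their
        # column dtypes; a zero-column table still has one row per setting
        return [
            {col: _scalarize(df[col].iloc[i]) for col in df.columns}
            for i in range(len(df))
        ]


def _scalarize(v: Any) -> Any:
    """Strip numpy scalar wrappers so hyperparameters serialize cleanly."""
    if isinstance(v, np.generic):
        return v.item()
    return v


@dataclass(frozen=True)
class BaseLearnerConfig:
    """One concrete base learner: a method and one complete hyperparameter setting."""

    method_name: str
    hyperparameters: Mapping[str, Any]
    learner_index: int

    def label(self) -> str:
        return f"{self.learner_index}:{self.method_name}"


@dataclass(frozen=True)
class EstimatorAdapter:
    """Pluggable fit/predict contract for one method family.

    ``builder(task, hyperparameters, random_state)`` returns an unfitted
    scikit-learn estimator.  ``fit`` and ``predict`` below give every adapter
    the same call shape regardless of the backing estimator; predictions of a
    fitted state on fixed X are deterministic given the seed recorded at build
    time.
    """

    name: str
    builder: Callable[[str, Mapping[str, Any], int], Any]
    tasks: tuple[str, ...] = (REGRESSION, CLASSIFICATION)

    def supports(self, task: str) -> bool:
        return task in self.tasks

    def build(self, task: str, hyperparameters: Mapping[str, Any], random_state: int) -> Any:
        if not self.supports(task):
            raise ConfigurationError(
                f"method '{self.name}' does not support task '{task}'"
            )
        try:
            return self.builder(task, dict(hyperparameters), random_state)
        except TypeError as exc:  # unknown hyperparameter name, wrong type, ...
            raise ConfigurationError(
                f"method '{self.name}' rejected hyperparameters {dict(hyperparameters)}: {exc}"
            ) from exc

    def fit(self, X: np.ndarray, y: np.ndarray,
            hyperparameters: Mapping[str, Any], task: str, random_state: int) -> Any:
        est = self.build(task, hyperparameters, random_state)
        est.fit(X, y)
        return est

    @staticmethod
    def predict(fitted: Any, X: np.ndarray) -> np.ndarray:
        pred = fitted.predict(X)
        return np.asarray(pred).reshape(len(X)) if len(X) else np.asarray(pred).reshape(0)


_REGISTRY: dict[str, EstimatorAdapter] = {}


def register_adapter(adapter: EstimatorAdapter, *, overwrite: bool = False) -> None:
    """Add an adapter to the runtime registry; the registry is user-extensible."""
    if adapter.name in _REGISTRY and not overwrite:
        raise ConfigurationError(f"adapter '{adapter.name}' is already registered")
    _REGISTRY[adapter.name] = adapter


def get_adapter(method_name: str) -> EstimatorAdapter:
    try:
        return _REGISTRY[method_name]
    except KeyError:
        known = ", ".join(sorted(_REGISTRY))
        raise ConfigurationError(
            f"unknown method '{method_name}'; registered methods: {known}"
        ) from None


def available_methods() -> list[str]:
    return sorted(_REGISTRY)


def expand_base_learners(specs: Sequence[MethodSpec]) -> list[BaseLearnerConfig]:
    """Expand method specs into the ordered flat list of base learners.

    One :class:`BaseLearnerConfig` is produced per row of each spec's
    hyperparameter table, in spec order then row order, so the total number of
    base learners is the sum of the row counts.  Every method name must
    resolve to a registered adapter.
    """
    specs = list(specs)
    if not specs:
        raise ConfigurationError("at least one base-learner spec is required")
    configs: list[BaseLearnerConfig] = []
    for spec in specs:
        get_adapter(spec.method_name)  # raises on unknown method
        for row in spec.rows():
            configs.append(
                BaseLearnerConfig(
                    method_name=spec.method_name,
                    hyperparameters=row,
                    learner_index=len(configs),
                )
            )
    return configs


def cartesian_grid(per_parameter_values: Mapping[str, Iterable[Any]]) -> pd.DataFrame:
    """Build the full hyperparameter combination table.

    Rows enumerate the Cartesian product of the per-parameter value lists, in
    lexicographic order with respect to the parameter-name order given, so the
    row count is the product of the list lengths.
    """
    if not per_parameter_values:
        raise ConfigurationError("cartesian_grid requires at least one parameter")
    names = list(per_parameter_values)
    value_lists = [list(per_parameter_values[n]) for n in names]
    for n, vals in zip(names, value_lists):
        if not vals:
            raise ConfigurationError(f"parameter '{n}' has an empty value list")
    rows = [dict(zip(names, combo)) for combo in itertools.product(*value_lists)]
    return pd.DataFrame(rows, columns=names)


# ---------------------------------------------------------------------------
# Built-in adapters.  The method families mirror the usual genomic-prediction
# rosters: random forest, gradient boosting, SVM (radial and polynomial),
# elastic net and partial least squares, plus deterministic baselines used in
# tests and as degenerate-input probes.
# ---------------------------------------------------------------------------

def _random_forest(task, hp, rs):
    cls = RandomForestRegressor if task == REGRESSION else RandomForestClassifier
    return cls(random_state=rs, **hp)


def _gradient_boosting(task, hp, rs):
    cls = GradientBoostingRegressor if task == REGRESSION else GradientBoostingClassifier
    return cls(random_state=rs, **hp)


def _svm(kernel):
    def build(task, hp, rs):
        if task == REGRESSION:
            return SVR(kernel=kernel, **hp)
        return SVC(kernel=kernel, random_state=rs, **hp)

    return build


def _elastic_net(task, hp, rs):
    if task == REGRESSION:
        return ElasticNet(random_state=rs, max_iter=10_000, **hp)
    hp = dict(hp)
    hp.setdefault("l1_ratio", 0.5)
    return LogisticRegression(solver="saga", max_iter=5_000, random_state=rs, **hp)


class _RavelPLS(PLSRegression):
    def predict(self, X):  # noqa: D102 - flatten the (n, 1) output
        return super().predict(X).ravel()


def _pls(task, hp, rs):
    return _RavelPLS(**hp)


def _linear(task, hp, rs):
    if task == REGRESSION:
        return LinearRegression(**hp)
    return LogisticRegression(C=np.inf, max_iter=5_000, random_state=rs, **hp)


def _dummy_mean(task, hp, rs):
    if task == REGRESSION:
        return DummyRegressor(strategy="mean", **hp)
    return DummyClassifier(strategy="most_frequent", random_state=rs, **hp)


def _dummy_median(task, hp, rs):
    return DummyRegressor(strategy="median", **hp)


for _adapter in [
    EstimatorAdapter("random_forest", _random_forest),
    EstimatorAdapter("gradient_boosting", _gradient_boosting),
    EstimatorAdapter("svm_rbf", _svm("rbf")),
    EstimatorAdapter("svm_poly", _svm("poly")),
    EstimatorAdapter("elastic_net", _elastic_net),
    EstimatorAdapter("pls", _pls, tasks=(REGRESSION,)),
    EstimatorAdapter("linear", _linear),
    EstimatorAdapter("dummy_mean", _dummy_mean),
    EstimatorAdapter("dummy_median", _dummy_median, tasks=(REGRESSION,)),
]:
    register_adapter(_adapter)
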