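"""Benchmark harness: stacking versus its base methods run standalone.

Each replicate simulates a fresh train/test pair (paired seeds, so every
method sees identical data), trains the full stack, trains every base method
family standalone on the full training set, and scores all of them on the
test set with the scenario's metric.

A standalone comparator with a multi-row hyperparameter table picks its row
by internal cross-validation over the table (refit on the full training set);
a single-row method is fitted directly.  Stacking never sees the test data
before scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV

from .estimators import SpecLike, as_method_spec, as_method_specs, train_stacking
from .exceptions import InputError
from .metrics import cohen_kappa, pearson_correlation
from .prediction import predict_stacking
from .registry import CLASSIFICATION, REGRESSION, MethodSpec, get_adapter
from .seeding import NS_BENCH, derive_seed
from .simulate import simulate_classification, simulate_regression

logger = logging.getLogger(__name__)

METRICS = {"pearson_r": pearson_correlation, "kappa": cohen_kappa}


@dataclass
class BenchmarkScenario:
    """What to simulate, which methods to race, and how to score them."""

    base_learners: Sequence[SpecLike]
    meta_learner: SpecLike = "elastic_net"
    task: str = REGRESSION
    n_train: int = 1000
    n_test: int = 1000
    p: int = 200
    n_causal: int = 20
    snr: float = 4.0
    n_classes: int = 4
    nfold: int = 5
    train_each_fold: bool = False
    metric: str = "pearson_r"

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise InputError(f"unknown metric '{self.metric}'; choose from {sorted(METRICS)}")
        if self.task not in (REGRESSION, CLASSIFICATION):
            raise InputError(f"unknown task '{self.task}'")


@dataclass
class BenchmarkResult:
    """Per-method, per-replicate metric values (long format)."""

    table: pd.DataFrame  # columns: replicate, method, metric, value, failed
    metric: str
    seeds: list[int] = field(default_factory=list)

    def mean_by_method(self) -> pd.Series:
        ok = self.table[~self.table["failed"]]
        return ok.groupby("method")["value"].mean()

    def pivot(self) -> pd.DataFrame:
        return self.table.pivot(index="replicate", columns="method", values="value")


def _simulate(scenario: BenchmarkScenario, n: int, seed: int):
    if scenario.task == REGRESSION:
        return simulate_regression(n=n, p=scenario.p, n_causal=scenario.n_causal,
                                   snr=scenario.snr, seed=seed)
    return simulate_classification(n=n, p=scenario.p, n_causal=scenario.n_causal,
                                   n_classes=scenario.n_classes, snr=scenario.snr,
                                   seed=seed)


def _fit_standalone(spec: MethodSpec, X, y, task: str, nfold: int, seed: int):
    """Ordinary single-model fit of one method family on the full training set."""
    adapter = get_adapter(spec.method_name)
    rows = spec.rows()
    if len(rows) == 1:
        return adapter.fit(X, y, rows[0], task, seed)
    base_est = adapter.build(task, rows[0], seed)
    grid = [{k: [v] for k, v in row.items()} for row in rows]
    search = GridSearchCV(base_est, grid, cv=nfold, n_jobs=1, refit=True)
    search.fit(X, y)
    return search.best_estimator_


def reference_scenario(
    n_train: int = 400,
    n_test: int = 400,
    p: int = 100,
    n_causal: int = 20,
    snr: float = 4.0,
    nfold: int = 5,
) -> BenchmarkScenario:
    """The package's reference simulation race at desk scale.

    Five method families with compact grids against an elastic-net
    meta-learner, on the sparse-effects + neighbor-interactions generator.
    The default sizes (400 train / 400 test, p=100) keep a 10-replicate race
    to a few minutes on one CPU while preserving the qualitative picture of
    the full n=1000, p=200 design.
    """
    roster = [
        MethodSpec("elastic_net", [{"alpha": 0.01, "l1_ratio": 0.5},
                                   {"alpha": 0.1, "l1_ratio": 0.5}]),
        MethodSpec("random_forest", [{"n_estimators": 150, "max_features": "sqrt"},
                                     {"n_estimators": 150, "max_features": 0.3}]),
        MethodSpec("gradient_boosting", [{"n_estimators": 150, "learning_rate": 0.1,
                                          "max_depth": 2},
                                         {"n_estimators": 150, "learning_rate": 0.1,
                                          "max_depth": 3}]),
        MethodSpec("svm_rbf", [{"C": 1.0}, {"C": 10.0}]),
        MethodSpec("pls", [{"n_components": 5}, {"n_components": 20}]),
    ]
    return BenchmarkScenario(
        base_learners=roster,
        meta_learner=MethodSpec("elastic_net", [{"alpha": 0.01, "l1_ratio": 0.5}]),
        task=REGRESSION,
        n_train=n_train, n_test=n_test, p=p, n_causal=n_causal, snr=snr,
        nfold=nfold, metric="pearson_r",
    )


def run_benchmark(
    scenario: BenchmarkScenario,
    replicates: int = 20,
    seed: int = 0,
    cores: int = 1,
) -> BenchmarkResult:
    """Race stacking against its base methods over simulated replicates."""
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    specs = as_method_specs(scenario.base_learners)
    meta_spec = as_method_spec(scenario.meta_learner)
    score = METRICS[scenario.metric]
    records: list[dict[str, Any]] = []
    seeds: list[int] = []
    for r in range(replicates):
        train_seed = derive_seed(seed, NS_BENCH, r, 0)
        test_seed = derive_seed(seed, NS_BENCH, r, 1)
        fit_seed = derive_seed(seed, NS_BENCH, r, 2)
        seeds.append(train_seed)
        train = _simulate(scenario, scenario.n_train, train_seed)
        test = _simulate(scenario, scenario.n_test, test_seed)

        def record(method: str, value: Optional[float], failed: bool = False,
                   message: str = "") -> None:
            records.append({"replicate": r, "method": method,
                            "metric": scenario.metric,
                            "value": np.nan if value is None else float(value),
                            "failed": failed, "message": message})

        try:
            model = train_stacking(
                train.X, train.Y, n_folds=scenario.nfold, base_learners=specs,
                meta_learner=meta_spec, train_each_fold=scenario.train_each_fold,
                task=scenario.task, cores=cores, seed=fit_seed,
            )
            record("stacking", score(predict_stacking(test.X, model), test.Y))
        except Exception as exc:  # noqa: BLE001 - continue-and-report
            logger.warning("stacking failed on replicate %d: %s", r, exc)
            record("stacking", None, failed=True, message=str(exc))

        for k, spec in enumerate(specs):
            name = spec.method_name
            try:
                fitted = _fit_standalone(
                    spec, train.X, train.Y, scenario.task, scenario.nfold,
                    derive_seed(seed, NS_BENCH, r, 3 + k),
                )
                pred = get_adapter(name).predict(fitted, test.X)
                record(name, score(pred, test.Y))
            except Exception as exc:  # noqa: BLE001
                logger.warning("method %s failed on replicate %d: %s", name, r, exc)
                record(name, None, failed=True, message=str(exc))

    return BenchmarkResult(table=pd.DataFrame.from_records(records),
                           metric=scenario.metric, seeds=seeds)
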