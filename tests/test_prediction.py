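import numpy as np
import pandas as pd
import pytest

from stackle.base_training import train_base_models
from stackle.estimators import train_stacking
from stackle.exceptions import InputError
from stackle.folds import assign_folds
from stackle.prediction import (
    aggregate_per_learner,
    load_model,
    predict_base,
    predict_stacking,
    save_model,
)
from stackle.registry import MethodSpec, expand_base_learners

from _naive import naive_stack_predict


def _fit_base(X, Y, nfold, methods, seed=0):
    folds = assign_folds(len(Y), nfold, seed=seed)
    configs = expand_base_learners([MethodSpec(m) for m in methods])
    return train_base_models(X, Y, folds, configs, seed=seed)


class TestPredictBase:
    def test_raw_table_has_one_column_per_fold_model(self, toy_regression):
        """2 folds x 3 learners feed every test sample to 6 base models."""
        X, Y = toy_regression
        base, _ = _fit_base(X, Y, 2, ["dummy_mean", "dummy_median", "linear"])
        raw = predict_base(X[:4], base)
        assert raw.shape == (4, 6)

    def test_empty_input_keeps_column_structure(self, toy_regression):
        X, Y = toy_regression
        base, _ = _fit_base(X, Y, 2, ["dummy_mean", "linear"])
        raw = predict_base(X[:0], base)
        assert raw.shape == (0, 4)

    def test_constant_learners_propagate(self):
        """Constant fold models put their per-fold constants in every row."""
        X = np.arange(12, dtype=float).reshape(6, 2)
        Y = np.array([1.0, 1.0, 1.0, 5.0, 5.0, 5.0])
        base, _ = _fit_base(X, Y, 2, ["dummy_mean"], seed=0)
        raw = predict_base(X, base)
        for col in raw.columns:
            assert raw[col].nunique() == 1

    def test_feature_name_mismatch_listed(self, toy_regression):
        X, Y = toy_regression
        model = train_stacking(pd.DataFrame(X, columns=list("abcd")), Y,
                               n_folds=2, base_learners=["linear"],
                               meta_learner="linear", seed=0)
        bad = pd.DataFrame(X, columns=["a", "b", "c", "zz"])
        with pytest.raises(InputError, match="missing=\\['d'\\], extra=\\['zz'\\]"):
            predict_stacking(bad, model)


class TestAggregatePerLearner:
    def test_regression_mean_of_fold_models(self):
        raw = pd.DataFrame(
            {(0, 0): [1.0, 5.0], (0, 1): [3.0, 7.0]},
        )
        raw.columns = pd.MultiIndex.from_tuples(raw.columns, names=["learner", "fold"])
        agg = aggregate_per_learner(raw, "regression")
        np.testing.assert_array_equal(agg[0].to_numpy(), [2.0, 6.0])

    def test_classification_modal_category(self):
        rows = [["A", "A", "B", "A", "B"]]
        raw = pd.DataFrame(np.array(rows, dtype=object),
                           columns=pd.MultiIndex.from_tuples(
                               [(0, f) for f in range(5)], names=["learner", "fold"]))
        agg = aggregate_per_learner(raw, "classification")
        assert agg.iloc[0, 0] == "A"

    def test_modal_tie_broken_lexicographically(self):
        raw = pd.DataFrame(np.array([["B", "A"]], dtype=object),
                           columns=pd.MultiIndex.from_tuples(
                               [(0, 0), (0, 1)], names=["learner", "fold"]))
        assert aggregate_per_learner(raw, "classification").iloc[0, 0] == "A"

    def test_aggregated_value_within_fold_prediction_range(self, toy_regression):
        X, Y = toy_regression
        base, _ = _fit_base(X, Y, 3, ["linear", "dummy_mean"])
        raw = predict_base(X, base)
        agg = aggregate_per_learner(raw, "regression")
        for lrn in agg.columns:
            block = raw[lrn].to_numpy()
            assert (agg[lrn].to_numpy() >= block.min(axis=1) - 1e-12).all()
            assert (agg[lrn].to_numpy() <= block.max(axis=1) + 1e-12).all()


class TestPredictStacking:
    def test_matches_naive_reimplementation(self):
        """End-to-end oracle: the pipeline equals a literal loop over the
        training and prediction steps, coded independently."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((12, 4))
        Y = X[:, 0] + 0.3 * X[:, 1] + 0.05 * rng.standard_normal(12)
        newX = rng.standard_normal((7, 4))
        names = ["dummy_mean", "dummy_median", "linear"]
        model = train_stacking(X, Y, n_folds=2, base_learners=names,
                               meta_learner="linear", seed=11)
        _, expected = naive_stack_predict(
            X, Y, model.base.folds.fold_of_sample, names, newX
        )
        np.testing.assert_allclose(predict_stacking(newX, model), expected, atol=1e-8)

    def test_row_order_equivariance(self, toy_regression):
        X, Y = toy_regression
        model = train_stacking(X, Y, n_folds=3,
                               base_learners=["linear", "dummy_mean"],
                               meta_learner="linear", seed=2)
        perm = np.random.default_rng(1).permutation(len(X))
        np.testing.assert_allclose(predict_stacking(X, model)[perm],
                                   predict_stacking(X[perm], model), atol=1e-12)

    def test_per_fold_regression_averages_meta_outputs(self, toy_regression):
        """In per-fold mode the final value is the mean of the fold
        meta-models' outputs — verified against an explicit loop."""
        X, Y = toy_regression
        model = train_stacking(X, Y, n_folds=3, base_learners=["linear"],
                               meta_learner="linear", train_each_fold=True, seed=4)
        from stackle.registry import get_adapter

        raw = predict_base(X, model.base, model.feature_names)
        agg = aggregate_per_learner(raw, "regression")
        design = model.meta.encoder.transform(agg).to_numpy()
        per_fold = np.vstack([
            get_adapter("linear").predict(s, design) for s in model.meta.fitted_states
        ])
        np.testing.assert_allclose(predict_stacking(X, model),
                                   per_fold.mean(axis=0), atol=1e-12)

    def test_passthrough_chain_with_perfect_learner(self):
        """With a single perfectly predictive learner and an unpenalized
        linear meta-model, stacking reduces to that learner's aggregated
        predictions."""
        rng = np.random.default_rng(8)
        X = rng.standard_normal((30, 3))
        Y = 2.0 * X[:, 0] - X[:, 2]  # exactly linear, no noise
        model = train_stacking(X, Y, n_folds=3, base_learners=["linear"],
                               meta_learner="linear", seed=1)
        agg = aggregate_per_learner(
            predict_base(X, model.base, model.feature_names), "regression"
        )
        np.testing.assert_allclose(predict_stacking(X, model),
                                   agg[0].to_numpy(), atol=1e-6)


class TestPersistence:
    def test_round_trip_predictions_identical(self, tmp_path, toy_regression):
        X, Y = toy_regression
        model = train_stacking(X, Y, n_folds=2,
                               base_learners=[("random_forest", [{"n_estimators": 10}]),
                                              "linear"],
                               meta_learner="linear", seed=3)
        path = tmp_path / "model.stk"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(predict_stacking(X, model),
                                      predict_stacking(X, loaded))

    def test_manifest_is_human_readable(self, tmp_path, toy_regression):
        from stackle.prediction import read_manifest

        X, Y = toy_regression
        model = train_stacking(X, Y, n_folds=2, base_learners=["linear"],
                               meta_learner="linear", seed=3)
        path = tmp_path / "model.stk"
        save_model(model, path)
        manifest = read_manifest(path)
        assert manifest["nfold"] == 2
        assert manifest["task"] == "regression"
        assert manifest["base_learners"][0]["method"] == "linear"
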