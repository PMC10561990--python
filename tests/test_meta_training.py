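import numpy as np
import pandas as pd
import pytest

from stackle.base_training import MetaFeatureTable, train_base_models
from stackle.exceptions import InputError
from stackle.folds import assign_folds
from stackle.meta_training import build_meta_design, train_meta_model
from stackle.registry import MethodSpec, expand_base_learners, get_adapter


def _table(values, fold_of_row):
    df = pd.DataFrame(values)
    df.columns = range(df.shape[1])
    return MetaFeatureTable(values=df, fold_of_row=np.asarray(fold_of_row))


class TestBuildMetaDesign:
    def test_regression_full_passthrough(self):
        vals = np.arange(12.0).reshape(4, 3)
        table = _table(vals, [0, 0, 1, 1])
        design = build_meta_design(table, which_to_use=[0, 1, 2], task="regression")
        np.testing.assert_array_equal(design.to_numpy(), vals)

    def test_column_subset_in_given_order(self):
        vals = np.arange(20.0).reshape(4, 5)
        table = _table(vals, [0, 0, 1, 1])
        design = build_meta_design(table, which_to_use=[3, 1], task="regression")
        np.testing.assert_array_equal(design.to_numpy(), vals[:, [3, 1]])

    def test_classification_indicator_encoding_drops_reference(self):
        """A label column with K observed categories becomes K-1 indicators."""
        labels = np.array(["A", "B", "C", "A", "B", "C"], dtype=object)
        table = _table({0: labels}, [0, 0, 0, 1, 1, 1])
        design = build_meta_design(table, which_to_use=[0], task="classification")
        assert design.shape == (6, 2)  # 3 levels - 1 reference
        np.testing.assert_array_equal(design["c0=B"].to_numpy(),
                                      (labels == "B").astype(float))

    def test_empty_which_to_use_rejected(self):
        table = _table(np.zeros((4, 2)), [0, 0, 1, 1])
        with pytest.raises(InputError):
            build_meta_design(table, which_to_use=[], task="regression")

    def test_out_of_range_indices_rejected(self):
        table = _table(np.zeros((4, 2)), [0, 0, 1, 1])
        with pytest.raises(InputError, match=r"\[5\]"):
            build_meta_design(table, which_to_use=[0, 5], task="regression")


class TestTrainMetaModel:
    def _meta_features(self, n=20, L=3, nfold=4, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((n, L))
        folds = assign_folds(n, nfold, seed=seed)
        return _table(vals, folds.fold_of_sample), rng.standard_normal(n)

    def test_pooled_mode_fits_once(self):
        table, Y = self._meta_features()
        meta = train_meta_model(table, Y, "linear", train_each_fold=False)
        assert meta.nfits == 1

    def test_per_fold_mode_fits_nfold_models(self):
        table, Y = self._meta_features(nfold=4)
        meta = train_meta_model(table, Y, "linear", train_each_fold=True)
        assert meta.nfits == 4

    def test_per_fold_fits_partition_the_rows(self):
        """Across the per-fold meta-fits every training row is used exactly once."""
        table, Y = self._meta_features(n=23, nfold=5)
        used = [np.flatnonzero(table.fold_of_row == f) for f in range(5)]
        all_rows = np.concatenate(used)
        assert sorted(all_rows) == list(range(23))

    def test_perfect_predictor_recovered_by_linear_meta(self):
        """If one meta-feature column is an exact copy of Y, an unpenalized
        linear meta-model reproduces Y in sample."""
        rng = np.random.default_rng(1)
        Y = rng.standard_normal(16)
        table = _table({0: Y.copy()}, np.repeat([0, 1], 8))
        meta = train_meta_model(table, Y, "linear")
        design = build_meta_design(table, [0], "regression")
        pred = get_adapter("linear").predict(meta.fitted_states[0], design.to_numpy())
        np.testing.assert_allclose(pred, Y, atol=1e-10)

    def test_pooled_mode_invariant_to_joint_row_permutation(self):
        table, Y = self._meta_features(n=30)
        perm = np.random.default_rng(5).permutation(30)
        table_p = _table(table.values.to_numpy()[perm], table.fold_of_row[perm])
        m1 = train_meta_model(table, Y, "linear")
        m2 = train_meta_model(table_p, Y[perm], "linear")
        probe = build_meta_design(table, None, "regression").to_numpy()
        p1 = get_adapter("linear").predict(m1.fitted_states[0], probe)
        p2 = get_adapter("linear").predict(m2.fitted_states[0], probe)
        np.testing.assert_allclose(p1, p2, atol=1e-9)

    def test_constant_meta_feature_yields_constant_predictions(self):
        """Degenerate input: a single constant out-of-fold column can only
        produce constant stacking predictions."""
        table = _table(np.full((12, 1), 2.5), np.repeat([0, 1, 2], 4))
        Y = np.random.default_rng(0).standard_normal(12)
        meta = train_meta_model(table, Y, "linear")
        pred = get_adapter("linear").predict(
            meta.fitted_states[0], np.full((5, 1), 2.5)
        )
        np.testing.assert_allclose(pred, pred[0])

    def test_y_length_mismatch_rejected(self):
        table, Y = self._meta_features()
        with pytest.raises(InputError):
            train_meta_model(table, Y[:-1], "linear")

    def test_multi_row_meta_spec_rejected(self):
        table, Y = self._meta_features()
        with pytest.raises(InputError, match="exactly one"):
            train_meta_model(table, Y, MethodSpec("linear", [{"fit_intercept": True},
                                                             {"fit_intercept": False}]))


class TestClassificationMetaPath:
    def test_end_to_end_label_meta_features(self, toy_classification):
        X, Y = toy_classification
        folds = assign_folds(len(Y), 3, seed=0)
        configs = expand_base_learners(
            [MethodSpec("random_forest", [{"n_estimators": 15}]), MethodSpec("dummy_mean")]
        )
        _, meta_features = train_base_models(
            X, Y, folds, configs, task="classification", seed=0
        )
        # cells are labels, not probabilities
        observed = set(np.unique(meta_features.values.to_numpy().astype(object)))
        assert observed <= {"pos", "neg"}
        meta = train_meta_model(meta_features, Y, ("random_forest", {"n_estimators": 15}),
                                task="classification", seed=0)
        assert meta.nfits == 1 and meta.encoder.categories is not None

    def test_unseen_category_maps_to_zero_encoding_with_warning(self):
        labels = np.array(["A", "B", "A", "B"], dtype=object)
        table = _table({0: labels}, [0, 0, 1, 1])
        meta = train_meta_model(table, np.array(["y", "n", "y", "n"], dtype=object),
                                ("random_forest", {"n_estimators": 5}),
                                task="classification")
        new = pd.DataFrame({0: np.array(["C", "B"], dtype=object)})
        with pytest.warns(RuntimeWarning, match="unseen"):
            design = meta.encoder.transform(new)
        np.testing.assert_array_equal(design.to_numpy()[0], [0.0])
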