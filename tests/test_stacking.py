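"""The two-phase stacking protocol: folds, meta features, meta learner."""

import numpy as np
import pandas as pd
import pytest

from stackcast.features import SplitDatasets
from stackcast.stacking import (BaseLearnerSpec, MetaLearnerSpec, StackedModel,
                                assemble_new_datasets, fit_meta_learner,
                                fit_stacked_model, generate_meta_features,
                                grid_tune, make_estimator, plan_folds,
                                predict_stacked)


def constant_spec(name, c):
    return BaseLearnerSpec(name, "constant", {"c": c})


def make_split(n_train=60, n_test=20, n_feat=4, seed=0, signal=True):
    rng = np.random.default_rng(seed)
    idx = pd.date_range("2015-01-01", periods=n_train + n_test, freq="D")
    X = pd.DataFrame(rng.normal(size=(n_train + n_test, n_feat)),
                     columns=[f"f{i}" for i in range(n_feat)], index=idx)
    beta = rng.normal(size=n_feat)
    y = pd.Series((X.to_numpy() @ beta) * (3.0 if signal else 0.0)
                  + 50 + rng.normal(size=n_train + n_test), index=idx, name="y")
    groups = {c: ("calendar" if i < 2 else "environmental")
              for i, c in enumerate(X.columns)}
    return SplitDatasets(
        X_train=X.iloc[:n_train], y_train=y.iloc[:n_train],
        X_test=X.iloc[n_train:], y_test=y.iloc[n_train:],
        split_date=idx[n_train], groups=groups, norm_records={},
        onehot_categories={})


class TestPlanFolds:
    def test_exact_division_into_five_blocks(self):
        plan = plan_folds(1090, 5)
        sizes = [stop - start for start, stop in plan.bounds]
        assert sizes == [218] * 5

    def test_remainder_goes_to_earliest_folds(self):
        assert [b - a for a, b in plan_folds(7, 3).bounds] == [3, 2, 2]

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            plan_folds(4, 5)

    def test_blocks_partition_chronologically(self):
        plan = plan_folds(23, 4)
        all_idx = np.concatenate([plan.fold_indices(i) for i in range(4)])
        np.testing.assert_array_equal(all_idx, np.arange(23))


class TestMetaFeatures:
    def test_exactly_twenty_fits_for_four_learners_five_folds(self):
        split = make_split(n_train=100)
        specs = [constant_spec(f"c{i}", i) for i in range(4)]
        meta = generate_meta_features(specs, split, plan_folds(100, 5),
                                      key_columns=[])
        assert len(meta.fit_log) == 20
        assert {(r["learner"], r["fold"]) for r in meta.fit_log} == {
            (f"c{i}", f) for i in range(4) for f in range(5)}

    def test_constant_learner_produces_constant_meta_feature(self):
        split = make_split()
        specs = [constant_spec("c", 7.5), constant_spec("d", 1.0)]
        meta = generate_meta_features(specs, split, plan_folds(60, 5),
                                      key_columns=[])
        assert (meta.oof["c"] == 7.5).all()
        assert (meta.test_mean["c"] == 7.5).all()

    def test_test_meta_feature_is_fold_model_average(self):
        split = make_split()
        specs = [BaseLearnerSpec("R", "ridge", {"alpha": 0.5})]
        meta = generate_meta_features(specs, split, plan_folds(60, 3),
                                      key_columns=[])
        naive = meta.test_fold_preds["R"].to_numpy().mean(axis=1)
        np.testing.assert_allclose(meta.test_mean["R"].to_numpy(), naive,
                                   atol=1e-9)

    def test_matches_naive_double_loop_reference(self):
        """Oracle: an independent loop over folds and learners reproduces the
        out-of-fold and test meta features on a 60-row, 2-learner, 3-fold
        instance."""
        split = make_split(n_train=60, n_test=15, seed=3)
        specs = [BaseLearnerSpec("R1", "ridge", {"alpha": 0.3}),
                 BaseLearnerSpec("R2", "ridge", {"alpha": 3.0})]
        plan = plan_folds(60, 3)
        meta = generate_meta_features(specs, split, plan, key_columns=[],
                                      seed=11)

        Xtr = split.X_train.to_numpy(float)
        ytr = split.y_train.to_numpy(float)
        Xte = split.X_test.to_numpy(float)
        for j, spec in enumerate(specs):
            oof = np.empty(60)
            q = np.zeros((15, 3))
            for i in range(3):
                lo, hi = plan.bounds[i]
                mask = np.ones(60, bool)
                mask[lo:hi] = False
                est = make_estimator(spec, seed=11 + 1000 * j + i)
                est.fit(Xtr[mask], ytr[mask])
                oof[lo:hi] = est.predict(Xtr[lo:hi])
                q[:, i] = est.predict(Xte)
            np.testing.assert_allclose(meta.oof[spec.name].to_numpy(), oof,
                                       atol=1e-9)
            np.testing.assert_allclose(meta.test_mean[spec.name].to_numpy(),
                                       q.mean(axis=1), atol=1e-9)

    def test_out_of_fold_values_ignore_their_own_fold(self):
        """Corrupting one fold's labels leaves that fold's out-of-fold
        predictions unchanged (no leakage)."""
        split = make_split(n_train=60, seed=5)
        spec = [BaseLearnerSpec("R", "ridge", {"alpha": 1.0})]
        plan = plan_folds(60, 3)
        base = generate_meta_features(spec, split, plan, key_columns=[], seed=2)
        lo, hi = plan.bounds[1]
        y_corrupt = split.y_train.copy()
        y_corrupt.iloc[lo:hi] = 999.0
        corrupted = SplitDatasets(
            X_train=split.X_train, y_train=y_corrupt, X_test=split.X_test,
            y_test=split.y_test, split_date=split.split_date,
            groups=split.groups, norm_records={}, onehot_categories={})
        out = generate_meta_features(spec, corrupted, plan, key_columns=[],
                                     seed=2)
        np.testing.assert_allclose(out.oof["R"].iloc[lo:hi],
                                   base.oof["R"].iloc[lo:hi], atol=1e-9)


class TestAssemble:
    def test_column_layout_meta_then_key(self):
        split = make_split()
        specs = [constant_spec(f"c{i}", i) for i in range(4)]
        meta = generate_meta_features(specs, split, plan_folds(60, 5),
                                      key_columns=["f0", "f1"])
        (Xn, _), (Xt, _) = assemble_new_datasets(meta)
        assert list(Xn.columns) == ["M_c0", "M_c1", "M_c2", "M_c3", "f0", "f1"]
        assert list(Xt.columns) == list(Xn.columns)

    def test_empty_key_set_gives_meta_only_design(self):
        split = make_split()
        meta = generate_meta_features([constant_spec("c", 2)], split,
                                      plan_folds(60, 5), key_columns=[])
        (Xn, _), (Xt, _) = assemble_new_datasets(meta)
        assert Xn.shape[1] == 1 and Xt.shape[1] == 1

    def test_row_counts_preserved(self):
        split = make_split(n_train=48, n_test=12)
        meta = generate_meta_features([constant_spec("c", 2)], split,
                                      plan_folds(48, 4), key_columns=["f0"])
        (Xn, yn), (Xt, yt) = assemble_new_datasets(meta)
        assert len(Xn) == len(yn) == 48
        assert len(Xt) == len(yt) == 12

    def test_missing_key_column_rejected(self):
        split = make_split()
        with pytest.raises(KeyError):
            generate_meta_features([constant_spec("c", 2)], split,
                                   plan_folds(60, 5), key_columns=["nope"])


class TestMetaLearner:
    def test_uniform_weights_equal_unweighted_fit(self, tiny_design):
        X, y = tiny_design
        spec = MetaLearnerSpec(alpha=0.5, l1_ratio=0.5)
        a = fit_meta_learner((X, y), spec=spec)
        b = fit_meta_learner((X, y), weights=np.full(len(y), 3.0), spec=spec)
        np.testing.assert_allclose(a.coef_, b.coef_, atol=1e-8)

    def test_zero_penalty_matches_normal_equations(self, rng):
        """With both penalties off, the fit solves ordinary least squares on a
        5x2 design (oracle: the normal equations)."""
        X = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        y = pd.Series(rng.normal(size=5))
        model = fit_meta_learner((X, y), spec=MetaLearnerSpec(alpha=0.0))
        A = np.column_stack([np.ones(5), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y.to_numpy())
        assert model.intercept_ == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(model.coef_, beta[1:], atol=1e-8)

    def test_duplicated_row_equals_doubled_weight(self, tiny_design):
        X, y = tiny_design
        spec = MetaLearnerSpec(alpha=0.2, l1_ratio=0.4)
        X_dup = pd.concat([X, X.iloc[[0]]])
        y_dup = pd.concat([y, y.iloc[[0]]])
        a = fit_meta_learner((X_dup, y_dup), spec=spec)
        w = np.ones(len(y))
        w[0] = 2.0
        b = fit_meta_learner((X, y), weights=w, spec=spec)
        np.testing.assert_allclose(a.coef_, b.coef_, atol=1e-8)

    def test_invalid_weights_rejected(self, tiny_design):
        X, y = tiny_design
        with pytest.raises(ValueError):
            fit_meta_learner((X, y), weights=np.zeros(len(y)))
        with pytest.raises(ValueError):
            fit_meta_learner((X, y), weights=np.ones(len(y) - 1))


class TestPredictStacked:
    def _identity_meta(self, meta, specs, c):
        (Xn, yn), _ = assemble_new_datasets(meta)
        model = fit_meta_learner((Xn, yn), spec=MetaLearnerSpec(alpha=0.0))
        # overwrite with the identity map onto the first meta column
        model.coef_ = np.zeros(Xn.shape[1])
        model.coef_[0] = 1.0
        model.intercept_ = 0.0
        return StackedModel(specs=specs, fold_models=meta.fold_models,
                            meta_model=model,
                            key_columns=list(meta.X_train_key.columns),
                            meta_spec=MetaLearnerSpec(alpha=0.0),
                            feature_columns=meta.feature_columns)

    def test_constant_ensemble_identity_meta_predicts_constant(self):
        split = make_split()
        specs = [constant_spec("c", 42.0), constant_spec("d", 7.0)]
        meta = generate_meta_features(specs, split, plan_folds(60, 5),
                                      key_columns=["f0"])
        model = self._identity_meta(meta, specs, 42.0)
        np.testing.assert_allclose(predict_stacked(model, split.X_test), 42.0)

    def test_scoring_path_equals_preassembled_design(self):
        split = make_split(seed=9)
        specs = [BaseLearnerSpec("R1", "ridge", {"alpha": 0.3}),
                 BaseLearnerSpec("R2", "ridge", {"alpha": 2.0})]
        meta = generate_meta_features(specs, split, plan_folds(60, 5),
                                      key_columns=["f0", "f1"], seed=4)
        model = fit_stacked_model(meta, specs,
                                  meta_spec=MetaLearnerSpec(alpha=0.1))
        _, (Xt, _) = assemble_new_datasets(meta)
        direct = model.meta_model.predict(Xt.to_numpy(float))
        np.testing.assert_allclose(predict_stacked(model, split.X_test),
                                   direct, atol=1e-9)

    def test_missing_feature_column_rejected(self):
        split = make_split()
        specs = [constant_spec("c", 1.0)]
        meta = generate_meta_features(specs, split, plan_folds(60, 5),
                                      key_columns=["f0"])
        model = fit_stacked_model(meta, specs)
        with pytest.raises(KeyError):
            predict_stacked(model, split.X_test.drop(columns=["f2"]))


class TestGridTune:
    @staticmethod
    def _ridge_fit_predict(params, X_fit, y_fit, X_hold):
        est = make_estimator(BaseLearnerSpec("R", "ridge", params))
        est.fit(X_fit.to_numpy(float), y_fit.to_numpy(float))
        return est.predict(X_hold.to_numpy(float))

    def test_single_point_grid_selected_directly(self, tiny_design):
        X, y = tiny_design
        best, _ = grid_tune({"alpha": [2.5]}, self._ridge_fit_predict, X, y)
        assert best == {"alpha": 2.5}

    def test_true_generating_penalty_wins_grid(self, rng):
        """On clean linear data the unregularized end of the grid achieves
        the smallest holdout error, and the search must find it."""
        n = 120
        idx = pd.date_range("2015-01-01", periods=n)
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"), index=idx)
        y = pd.Series(X.to_numpy() @ [5.0, -3.0, 2.0], index=idx)
        grid = {"alpha": [1e-6, 1.0, 100.0]}
        maes = {}
        for a in grid["alpha"]:
            best, mae = grid_tune({"alpha": [a]}, self._ridge_fit_predict, X, y)
            maes[a] = mae
        best, best_mae = grid_tune(grid, self._ridge_fit_predict, X, y)
        assert best == {"alpha": 1e-6}
        assert all(best_mae <= m for m in maes.values())

    def test_ties_break_to_earlier_grid_point(self, tiny_design):
        X, y = tiny_design
        calls = []

        def fp(params, X_fit, y_fit, X_hold):
            calls.append(params["p"])
            return np.zeros(len(X_hold))

        best, _ = grid_tune({"p": [1, 2, 3]}, fp, X, y)
        assert best == {"p": 1}
        assert calls == [1, 2, 3]

    def test_empty_grid_rejected(self, tiny_design):
        X, y = tiny_design
        with pytest.raises(ValueError):
            grid_tune({}, self._ridge_fit_predict, X, y)

    def test_holdout_is_last_fifth(self, tiny_design):
        X, y = tiny_design
        seen = {}

        def fp(params, X_fit, y_fit, X_hold):
            seen["fit"], seen["hold"] = len(X_fit), len(X_hold)
            return np.zeros(len(X_hold))

        grid_tune({"p": [0]}, fp, X, y, holdout_fraction=0.2)
        assert seen == {"fit": 48, "hold": 12}


def test_end_to_end_stacking_is_seed_deterministic():
    split = make_split(n_train=80, n_test=20, seed=1)
    specs = [BaseLearnerSpec("R", "ridge", {"alpha": 1.0}),
             BaseLearnerSpec("RF", "random_forest", {"n_estimators": 10})]
    preds = []
    for _ in range(2):
        meta = generate_meta_features(specs, split, plan_folds(80, 4),
                                      key_columns=["f0"], seed=21)
        model = fit_stacked_model(meta, specs,
                                  meta_spec=MetaLearnerSpec(alpha=0.1))
        preds.append(predict_stacked(model, split.X_test))
    np.testing.assert_array_equal(preds[0], preds[1])
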