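"""Two-phase stacked generalization for daily count forecasting.

Phase one trains four heterogeneous base learners — ridge regression, random
forest, gradient-boosted trees and a feedforward network — under chronological
k-fold cross-validation.  Each learner's out-of-fold predictions on the
training rows (``M_j``) become meta features; its k fold models are averaged
on the test rows (``N_j``).  Key original columns (by default the calendar
and lagged-admissions groups) are passed through alongside.  Phase two fits
an elastic-net meta learner, optionally sample-weighted, on the assembled
meta design.

Hyperparameters are tuned by grid search against the chronologically last
20% of the relevant training design (holdout MAE).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression, Ridge
from sklearn.neural_network import MLPRegressor

from .features import SplitDatasets

logger = logging.getLogger(__name__)

__all__ = [
    "BaseLearnerSpec",
    "MetaLearnerSpec",
    "FoldPlan",
    "MetaFeatureSet",
    "StackedModel",
    "default_base_learners",
    "plan_folds",
    "make_estimator",
    "generate_meta_features",
    "assemble_new_datasets",
    "fit_meta_learner",
    "predict_stacked",
    "grid_tune",
    "key_feature_columns",
]

FAMILIES = ("ridge", "random_forest", "gradient_boosted_trees", "feedforward_network")


@dataclass
class BaseLearnerSpec:
    """One first-phase regressor: family, fixed hyperparameters, tuning grid."""

    name: str
    family: str
    params: dict[str, Any] = field(default_factory=dict)
    grid: dict[str, Sequence[Any]] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES and self.family != "constant":
            raise ValueError(f"unknown learner family {self.family!r}")

    def with_params(self, **params) -> "BaseLearnerSpec":
        return replace(self, params={**self.params, **params})


@dataclass
class MetaLearnerSpec:
    """The elastic-net meta learner: squared error + combined L1/L2 penalty."""

    alpha: float = 0.01
    l1_ratio: float = 0.5
    grid: dict[str, Sequence[Any]] = field(default_factory=dict)


class _ConstantRegressor:
    """Degenerate learner predicting a fixed constant; used in structural tests."""

    def __init__(self, c: float = 0.0):
        self.c = c

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(len(X), float(self.c))


def default_base_learners(seed: int = 0,
                          reduced: bool = False) -> list[BaseLearnerSpec]:
    """The four standard base learners with sensible tabular defaults.

    ``reduced=True`` shrinks ensemble sizes and network iterations for quick
    benchmark runs; families and structure are unchanged.
    """
    rf_n, gb_n, ann_iter = (100, 100, 500) if reduced else (200, 150, 800)
    return [
        BaseLearnerSpec("Ridge", "ridge", {"alpha": 1.0},
                        grid={"alpha": [0.1, 1.0, 10.0]}),
        BaseLearnerSpec("RF", "random_forest",
                        {"n_estimators": rf_n, "min_samples_leaf": 2},
                        grid={"min_samples_leaf": [1, 2, 4]}),
        BaseLearnerSpec("GBDT", "gradient_boosted_trees",
                        {"n_estimators": gb_n, "max_depth": 3,
                         "learning_rate": 0.1},
                        grid={"max_depth": [2, 3]}),
        BaseLearnerSpec("ANN", "feedforward_network",
                        {"hidden_layer_sizes": (128,), "alpha": 1e-2,
                         "batch_size": 64, "learning_rate_init": 0.005,
                         "max_iter": ann_iter},
                        grid={"alpha": [1e-3, 1e-2]}),
    ]


def make_estimator(spec: BaseLearnerSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator behind a learner spec."""
    p = dict(spec.params)
    if spec.family == "ridge":
        return Ridge(**p)
    if spec.family == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **p)
    if spec.family == "gradient_boosted_trees":
        return GradientBoostingRegressor(random_state=seed, **p)
    if spec.family == "feedforward_network":
        p.setdefault("hidden_layer_sizes", (64,))
        p.setdefault("activation", "relu")
        p.setdefault("early_stopping", True)
        p.setdefault("validation_fraction", 0.1)
        p.setdefault("n_iter_no_change", 25)
        p.setdefault("max_iter", 500)
        return MLPRegressor(random_state=seed, **p)
    if spec.family == "constant":
        return _ConstantRegressor(**p)
    raise ValueError(f"unknown learner family {spec.family!r}")


@dataclass(frozen=True)
class FoldPlan:
    """Contiguous chronological fold boundaries partitioning the training rows."""

    n_rows: int
    k: int
    bounds: tuple[tuple[int, int], ...]  # half-open [start, stop) per fold

    def fold_indices(self, i: int) -> np.ndarray:
        start, stop = self.bounds[i]
        return np.arange(start, stop)

    def complement_indices(self, i: int) -> np.ndarray:
        start, stop = self.bounds[i]
        return np.concatenate([np.arange(0, start), np.arange(stop, self.n_rows)])


def plan_folds(n_rows: int, k: int = 5) -> FoldPlan:
    """Split ``n_rows`` chronologically into k contiguous blocks.

    When ``n_rows`` is not divisible by k, the earlier folds receive the
    extra rows, so block sizes differ by at most one and decrease in time.
    """
    if n_rows < k:
        raise ValueError(f"cannot split {n_rows} rows into {k} folds")
    base, extra = divmod(n_rows, k)
    bounds = []
    start = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        bounds.append((start, start + size))
        start += size
    return FoldPlan(n_rows=n_rows, k=k, bounds=tuple(bounds))


@dataclass
class MetaFeatureSet:
    """Out-of-fold meta features and fold-averaged test features.

    ``oof[name]`` is the learner's prediction for every training row made by
    the fold model that excluded that row's fold (the concatenation of the
    per-fold out-of-fold prediction vectors).  ``test_fold_preds[name]`` holds
    one column per fold model evaluated on the test rows; ``test_mean[name]``
    is their arithmetic mean.
    """

    learner_names: list[str]
    oof: dict[str, pd.Series]
    test_fold_preds: dict[str, pd.DataFrame]
    test_mean: dict[str, pd.Series]
    fold_models: dict[str, list[Any]]
    X_train_key: pd.DataFrame
    X_test_key: pd.DataFrame
    y_train: pd.Series
    y_test: pd.Series
    fit_log: list[dict[str, Any]]
    plan: FoldPlan
    feature_columns: list[str] = field(default_factory=list)


def key_feature_columns(split: SplitDatasets,
                        groups: Sequence[str] = ("calendar", "HAs")) -> list[str]:
    """Columns passed through to the meta learner (default: calendar + HAs)."""
    return [c for c in split.X_train.columns if split.groups.get(c) in groups]


def generate_meta_features(specs: Sequence[BaseLearnerSpec],
                           split: SplitDatasets,
                           plan: FoldPlan,
                           key_columns: Sequence[str] | None = None,
                           seed: int = 0,
                           forward_chaining: bool = False) -> MetaFeatureSet:
    """Run the first stacking phase: 4 x k chronological out-of-fold fits.

    For fold i, learner j is trained on all training folds except i (the
    stated protocol; with ``forward_chaining=True`` only on folds before i,
    skipping fold 0) and predicts fold i and the test rows.  Performs exactly
    ``len(specs) * k`` fits, each recorded in ``fit_log``.
    """
    if plan.n_rows != len(split.X_train):
        raise ValueError("fold plan inconsistent with the training set")
    X_train = split.X_train.to_numpy(dtype=float)
    y_train = split.y_train.to_numpy(dtype=float)
    X_test = split.X_test.to_numpy(dtype=float)

    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("learner names must be distinct")

    oof: dict[str, pd.Series] = {}
    test_fold_preds: dict[str, pd.DataFrame] = {}
    test_mean: dict[str, pd.Series] = {}
    fold_models: dict[str, list[Any]] = {}
    fit_log: list[dict[str, Any]] = []

    for j, spec in enumerate(specs):
        oof_values = np.full(plan.n_rows, np.nan)
        q_cols = {}
        models = []
        for i in range(plan.k):
            if forward_chaining:
                if i == 0:
                    train_idx = np.array([], dtype=int)
                else:
                    train_idx = np.arange(0, plan.bounds[i][0])
            else:
                train_idx = plan.complement_indices(i)
            fold_idx = plan.fold_indices(i)
            model = make_estimator(spec, seed=seed + 1000 * j + i)
            if len(train_idx) == 0:
                # forward chaining has no history for the first fold; fall
                # back to the training-set mean so every row gets a value
                model = _ConstantRegressor(float(y_train.mean()))
            else:
                try:
                    model.fit(X_train[train_idx], y_train[train_idx])
                except Exception as exc:  # pragma: no cover - defensive
                    raise RuntimeError(
                        f"base learner {spec.name!r} failed on fold {i}: {exc}"
                    ) from exc
            preds = np.asarray(model.predict(X_train[fold_idx]), dtype=float)
            q = np.asarray(model.predict(X_test), dtype=float)
            if not (np.isfinite(preds).all() and np.isfinite(q).all()):
                raise RuntimeError(
                    f"base learner {spec.name!r} produced non-finite predictions "
                    f"on fold {i}")
            oof_values[fold_idx] = preds
            q_cols[f"fold_{i}"] = q
            models.append(model)
            fit_log.append({"learner": spec.name, "fold": i,
                            "n_train_rows": int(len(train_idx))})
            logger.info("fit %s fold %d on %d rows", spec.name, i, len(train_idx))
        oof[spec.name] = pd.Series(oof_values, index=split.X_train.index,
                                   name=f"M_{spec.name}")
        test_fold_preds[spec.name] = pd.DataFrame(q_cols, index=split.X_test.index)
        test_mean[spec.name] = pd.Series(
            test_fold_preds[spec.name].mean(axis=1).to_numpy(),
            index=split.X_test.index, name=f"N_{spec.name}")
        fold_models[spec.name] = models

    if key_columns is None:
        key_columns = key_feature_columns(split)
    missing = [c for c in key_columns if c not in split.X_train.columns]
    if missing:
        raise KeyError(f"key columns absent from the design: {missing}")

    return MetaFeatureSet(
        learner_names=names, oof=oof, test_fold_preds=test_fold_preds,
        test_mean=test_mean, fold_models=fold_models,
        X_train_key=split.X_train[list(key_columns)],
        X_test_key=split.X_test[list(key_columns)],
        y_train=split.y_train, y_test=split.y_test,
        fit_log=fit_log, plan=plan,
        feature_columns=list(split.X_train.columns))


def assemble_new_datasets(meta: MetaFeatureSet,
                          key_columns: Sequence[str] | None = None,
                          ) -> tuple[tuple[pd.DataFrame, pd.Series],
                                     tuple[pd.DataFrame, pd.Series]]:
    """Build the second-phase designs: (M_1..M_4, key) and (N_1..N_4, key)."""
    if key_columns is None:
        X_tr_key, X_te_key = meta.X_train_key, meta.X_test_key
    else:
        for c in key_columns:
            if c not in meta.X_train_key.columns:
                raise KeyError(f"key column {c!r} not available")
        X_tr_key = meta.X_train_key[list(key_columns)]
        X_te_key = meta.X_test_key[list(key_columns)]
    meta_tr = pd.DataFrame({f"M_{n}": meta.oof[n] for n in meta.learner_names})
    meta_te = pd.DataFrame({f"M_{n}": meta.test_mean[n] for n in meta.learner_names})
    X_new_train = pd.concat([meta_tr, X_tr_key], axis=1)
    X_new_test = pd.concat([meta_te, X_te_key], axis=1)
    return (X_new_train, meta.y_train), (X_new_test, meta.y_test)


@dataclass
class StackedModel:
    """A fitted stacked ensemble ready to score raw design rows."""

    specs: list[BaseLearnerSpec]
    fold_models: dict[str, list[Any]]
    meta_model: Any
    key_columns: list[str]
    meta_spec: MetaLearnerSpec
    feature_columns: list[str]

    def meta_design(self, X: pd.DataFrame) -> pd.DataFrame:
        """Fold-average each base learner on X and append the key features."""
        missing = [c for c in self.feature_columns if c not in X.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        Xa = X[self.feature_columns].to_numpy(dtype=float)
        cols = {}
        for spec in self.specs:
            preds = np.mean(
                [m.predict(Xa) for m in self.fold_models[spec.name]], axis=0)
            cols[f"M_{spec.name}"] = preds
        design = pd.DataFrame(cols, index=X.index)
        return pd.concat([design, X[self.key_columns]], axis=1)


def fit_meta_learner(s_new_train: tuple[pd.DataFrame, pd.Series],
                     weights: np.ndarray | pd.Series | None = None,
                     spec: MetaLearnerSpec | None = None,
                     seed: int = 0):
    """Fit the elastic-net meta learner, optionally sample-weighted.

    With both penalties zero the problem is ordinary least squares and is
    solved exactly (the coordinate-descent solver is undefined at alpha=0).
    """
    X, y = s_new_train
    spec = spec or MetaLearnerSpec()
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(y):
            raise ValueError("weights misaligned with training rows")
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be strictly positive and finite")
    else:
        w = None
    if spec.alpha == 0:
        model = LinearRegression()
    else:
        model = ElasticNet(alpha=spec.alpha, l1_ratio=spec.l1_ratio,
                           max_iter=50_000, random_state=seed)
    model.fit(X.to_numpy(dtype=float), np.asarray(y, dtype=float),
              sample_weight=w)
    return model


def predict_stacked(model: StackedModel, X: pd.DataFrame) -> np.ndarray:
    """Score raw design rows through the full two-phase pipeline.

    Predictions are real-valued counts; they are deliberately not rounded,
    since the evaluation metrics are computed on the continuous scale.
    """
    design = model.meta_design(X)
    return np.asarray(model.meta_model.predict(design.to_numpy(dtype=float)),
                      dtype=float)


def fit_stacked_model(meta: MetaFeatureSet, specs: Sequence[BaseLearnerSpec],
                      weights=None, meta_spec: MetaLearnerSpec | None = None,
                      seed: int = 0) -> StackedModel:
    """Assemble the meta design, fit the meta learner, return the bundle."""
    (X_new_train, y_train), _ = assemble_new_datasets(meta)
    meta_model = fit_meta_learner((X_new_train, y_train), weights=weights,
                                  spec=meta_spec, seed=seed)
    return StackedModel(
        specs=list(specs), fold_models=meta.fold_models,
        meta_model=meta_model, key_columns=list(meta.X_train_key.columns),
        meta_spec=meta_spec or MetaLearnerSpec(),
        feature_columns=list(meta.feature_columns))


def grid_tune(grid: dict[str, Sequence[Any]],
              fit_predict: Callable[[dict[str, Any], pd.DataFrame, pd.Series,
                                     pd.DataFrame], np.ndarray],
              X: pd.DataFrame, y: pd.Series,
              holdout_fraction: float = 0.2) -> tuple[dict[str, Any], float]:
    """Grid search against the chronologically last ``holdout_fraction`` rows.

    ``fit_predict(params, X_fit, y_fit, X_holdout)`` fits one candidate and
    returns holdout predictions.  The combination minimizing holdout MAE
    wins; ties go to the earlier grid point (itertools.product order over the
    grid dict).  The winner is returned, not refit.
    """
    if not grid:
        raise ValueError("empty grid")
    n = len(X)
    n_hold = max(1, int(round(holdout_fraction * n)))
    if n_hold >= n:
        raise ValueError("holdout leaves no fitting rows")
    X_fit, X_hold = X.iloc[:n - n_hold], X.iloc[n - n_hold:]
    y_fit, y_hold = y.iloc[:n - n_hold], y.iloc[n - n_hold:]

    keys = list(grid.keys())
    best_params, best_mae = None, np.inf
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        preds = np.asarray(fit_predict(params, X_fit, y_fit, X_hold), dtype=float)
        mae = float(np.mean(np.abs(np.asarray(y_hold, dtype=float) - preds)))
        if mae < best_mae:
            best_params, best_mae = params, mae
    return best_params, best_mae


def tune_base_learner(spec: BaseLearnerSpec, X: pd.DataFrame, y: pd.Series,
                      holdout_fraction: float = 0.2,
                      seed: int = 0) -> BaseLearnerSpec:
    """Tune one base learner's grid on the training design; fixed params win ties."""
    if not spec.grid:
        return spec

    def fit_predict(params, X_fit, y_fit, X_hold):
        est = make_estimator(spec.with_params(**params), seed=seed)
        est.fit(X_fit.to_numpy(dtype=float), np.asarray(y_fit, dtype=float))
        return est.predict(X_hold.to_numpy(dtype=float))

    best, _ = grid_tune(spec.grid, fit_predict, X, y, holdout_fraction)
    return spec.with_params(**best)


def tune_meta_learner(spec: MetaLearnerSpec, X_new: pd.DataFrame, y: pd.Series,
                      weights=None, holdout_fraction: float = 0.2,
                      seed: int = 0) -> MetaLearnerSpec:
    """Tune the elastic net's (alpha, l1_ratio) grid on the new training design."""
    if not spec.grid:
        return spec
    w = None if weights is None else np.asarray(weights, dtype=float)

    def fit_predict(params, X_fit, y_fit, X_hold):
        cand = MetaLearnerSpec(alpha=params.get("alpha", spec.alpha),
                               l1_ratio=params.get("l1_ratio", spec.l1_ratio))
        w_fit = None if w is None else w[:len(X_fit)]
        model = fit_meta_learner((X_fit, y_fit), weights=w_fit, spec=cand,
                                 seed=seed)
        return model.predict(X_hold.to_numpy(dtype=float))

    best, _ = grid_tune(spec.grid, fit_predict, X_new, y, holdout_fraction)
    return MetaLearnerSpec(alpha=best.get("alpha", spec.alpha),
                           l1_ratio=best.get("l1_ratio", spec.l1_ratio),
                           grid=spec.grid)
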