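"""End-to-end experiment: simulate → preprocess → tune → stack → LDS → evaluate → explain.

A single global seed fans out to named sub-seeds (generator, fold models,
network initialization, explainer background and permutations) so each stage
can be reproduced in isolation and two runs of the same configuration are
identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as io_mod
from .evaluation import comparison_table, compute_metrics
from .explain import (aggregate_variable_shap, global_importance,
                      infer_feature_groups, partial_prediction_metrics,
                      shapley_attributions, three_part_decomposition)
from .features import LagSpec, prepare_datasets
from .lds import LDSConfig, compute_weights
from .stacking import (MetaLearnerSpec, default_base_learners, fit_stacked_model,
                       generate_meta_features, key_feature_columns, plan_folds,
                       predict_stacked, tune_base_learner, tune_meta_learner)
from .synthetic import GeneratorConfig, default_holidays, generate_panel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_experiment", "derive_seed"]


def derive_seed(seed: int, name: str) -> int:
    """A stable named sub-seed below 2**31, derived from the global seed."""
    return (seed * 1_000_003 + sum(ord(c) for c in name) * 7919) % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    panel_path: str | None = None  # None -> simulate
    output_dir: str | None = None
    n_days: int = 1461
    lag: int = 6
    split_date: str = "2018-01-01"
    k_folds: int = 5
    use_lds: bool = True
    lds: LDSConfig = field(default_factory=LDSConfig)
    tune: bool = True  # grid-tune the base learners
    tune_meta: bool = True  # grid-tune the elastic net
    reduced_learners: bool = False
    meta_grid: dict = field(default_factory=lambda: {
        "alpha": [0.01, 0.1, 1.0], "l1_ratio": [0.1, 0.5, 0.9]})
    explain: bool = False
    explain_background: int = 60
    explain_samples: int = 40
    explain_permutations: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        lds_data = data.pop("lds", None)
        cfg = cls(**data)
        if lds_data:
            cfg.lds = LDSConfig(**lds_data)
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def run_experiment(config: RunConfig) -> dict:
    """Run the full pipeline and return (and optionally write) the report.

    The report dict carries the comparison table, the fit audit log (one
    record per base-learner/fold fit), LDS weights, and, when enabled, the
    explanation exports.
    """
    seed = config.seed
    if config.panel_path:
        panel = io_mod.load_panel_csv(config.panel_path)
    else:
        panel = generate_panel(GeneratorConfig(
            n_days=config.n_days, seed=derive_seed(seed, "generator")))
    years = range(pd.to_datetime(panel["date"]).dt.year.min(),
                  pd.to_datetime(panel["date"]).dt.year.max() + 1)
    holidays = default_holidays(years, seed=derive_seed(seed, "holidays"))

    split = prepare_datasets(panel, LagSpec(config.lag), holidays,
                             config.split_date)
    specs = default_base_learners(seed=derive_seed(seed, "learners"),
                                  reduced=config.reduced_learners)
    if config.tune:
        specs = [tune_base_learner(s, split.X_train, split.y_train,
                                   seed=derive_seed(seed, f"tune-{s.name}"))
                 for s in specs]

    plan = plan_folds(len(split.X_train), config.k_folds)
    key_cols = key_feature_columns(split)
    meta = generate_meta_features(specs, split, plan, key_columns=key_cols,
                                  seed=derive_seed(seed, "folds"))

    weights = None
    lds_export = None
    if config.use_lds:
        sw = compute_weights(split.y_train, config=config.lds)
        weights = sw.weights.to_numpy()
        lds_export = sw

    meta_spec = MetaLearnerSpec(grid=config.meta_grid)
    if config.tune_meta:
        from .stacking import assemble_new_datasets
        (X_new_train, y_tr), _ = assemble_new_datasets(meta)
        meta_spec = tune_meta_learner(meta_spec, X_new_train, y_tr,
                                      weights=weights,
                                      seed=derive_seed(seed, "meta"))
    model = fit_stacked_model(meta, specs, weights=weights,
                              meta_spec=meta_spec,
                              seed=derive_seed(seed, "meta-fit"))

    y_test = split.y_test.to_numpy(dtype=float)
    predictions = {name: meta.test_mean[name].to_numpy()
                   for name in meta.learner_names}
    label = "Stacking + LDS" if config.use_lds else "Stacking"
    predictions[label] = predict_stacked(model, split.X_test)
    table = comparison_table(predictions, y_test,
                             reference_models=list(meta.learner_names))

    report: dict = {
        "config": dataclasses.asdict(config),
        "fit_log": meta.fit_log,
        "metrics": {name: compute_metrics(y_test, yhat).as_dict()
                    for name, yhat in predictions.items()},
        "comparison_table": table,
        "model": model,
        "split": split,
        "meta_features": meta,
        "weights": None if weights is None else lds_export,
    }

    if config.explain:
        rng = np.random.default_rng(derive_seed(seed, "background"))
        bg_idx = rng.choice(len(split.X_train),
                            size=min(config.explain_background,
                                     len(split.X_train)), replace=False)
        background = split.X_train.iloc[np.sort(bg_idx)]
        # spread explained samples evenly across the test period so local
        # explanations cover all seasons
        n_expl = min(config.explain_samples, len(split.X_test))
        stride_idx = np.unique(np.linspace(0, len(split.X_test) - 1, n_expl,
                                           dtype=int))
        explain_rows = split.X_test.iloc[stride_idx]
        shap_report = shapley_attributions(
            lambda X: predict_stacked(model, X), background, explain_rows,
            seed=derive_seed(seed, "permutation"),
            n_permutations=config.explain_permutations)
        groups = infer_feature_groups(split.X_train.columns, split.groups)
        var_report = aggregate_variable_shap(shap_report, groups)
        decomp = three_part_decomposition(var_report, groups)
        report["shap"] = {
            "feature_report": shap_report,
            "variable_report": var_report,
            "importance": global_importance(var_report),
            "decomposition": decomp,
            "partial_metrics": partial_prediction_metrics(
                decomp, split.y_test.loc[decomp.index]),
        }

    if config.output_dir:
        _write_outputs(report, config)
    return report


def _write_outputs(report: dict, config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report["comparison_table"].to_csv(outdir / "comparison_table.csv")
    (outdir / "metrics.json").write_text(
        json.dumps(report["metrics"], indent=2, sort_keys=True))
    (outdir / "fit_log.json").write_text(json.dumps(report["fit_log"], indent=2))
    if report["weights"] is not None:
        sw = report["weights"]
        pd.DataFrame({"weight": sw.weights,
                      "effective_density": sw.effective_density,
                      "stratum": sw.strata}).to_csv(
            outdir / "lds_weights.csv", index_label="date")
    if "shap" in report:
        report["shap"]["decomposition"].to_csv(
            outdir / "decomposition.csv", index_label="date")
        report["shap"]["importance"].to_csv(
            outdir / "importance.csv", index=False)
        report["shap"]["partial_metrics"].to_csv(outdir / "partial_metrics.csv")
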