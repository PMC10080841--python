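"""Shapley-value attribution of stacked forecasts to interpretable inputs.

Attributions are computed on the original (preprocessed) design columns, not
on the meta features, so the explanation speaks the language of the inputs —
temperature lags, pollutant lags, calendar indicators.  The estimator is a
permutation chain: for a random feature ordering, background rows are morphed
one feature at a time into the explained row, and each feature is credited
with the mean prediction change at its step.  Averaged over orderings and
background rows this estimates the Shapley value, and by construction the
base value (mean background prediction) plus all attributions reconstructs
the model prediction exactly — the additivity law that every downstream
aggregation in this module preserves.

Per-column attributions are aggregated per underlying variable (all ``TEM
Lag x`` and ``TEM Lag 1L mean/std`` columns sum into ``TEM``) and variables
roll up into three additive parts: the base value, a *regular* difference
from calendar and historical-admission features, and a *volatile* difference
from environmental features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluation import EvalReport, compute_metrics, relative_improvement

__all__ = [
    "FeatureGroups",
    "ShapReport",
    "infer_feature_groups",
    "shapley_attributions",
    "aggregate_variable_shap",
    "global_importance",
    "three_part_decomposition",
    "partial_prediction_metrics",
    "local_waterfall",
    "dependence_export",
]

CALENDAR_VARIABLES = {"DOW", "MON", "SEA", "YEAR", "TS", "HOL", "WD", "FWD", "LWD"}


@dataclass
class FeatureGroups:
    """column -> underlying variable, and variable -> additive part."""

    column_to_variable: dict[str, str]
    variable_to_part: dict[str, str]  # part in {"HAs", "calendar", "environmental"}

    def variables(self) -> list[str]:
        seen: list[str] = []
        for v in self.column_to_variable.values():
            if v not in seen:
                seen.append(v)
        return seen


def infer_feature_groups(columns, groups: dict[str, str]) -> FeatureGroups:
    """Derive the variable/part mapping from design column names and tags.

    ``"TEM Lag 3"`` and ``"TEM Lag 1L mean"`` map to variable ``TEM``;
    one-hot columns ``"DOW_3"`` map to ``DOW``; plain calendar columns map to
    themselves.  Parts follow the design group tags.
    """
    col_to_var: dict[str, str] = {}
    var_to_part: dict[str, str] = {}
    for col in columns:
        if col not in groups:
            raise KeyError(f"column {col!r} has no group tag")
        if " Lag" in col:
            var = col.split(" Lag")[0]
        elif "_" in col and col.split("_")[0] in CALENDAR_VARIABLES:
            var = col.split("_")[0]
        else:
            var = col
        col_to_var[col] = var
        part = groups[col]
        if part not in ("HAs", "calendar", "environmental"):
            raise ValueError(f"column {col!r} has unexpected group {part!r}")
        var_to_part[var] = part
    return FeatureGroups(col_to_var, var_to_part)


@dataclass
class ShapReport:
    """Base value plus per-sample attributions, at column or variable level."""

    base_value: float
    values: pd.DataFrame  # samples x (columns | variables)
    X_explain: pd.DataFrame  # the explained rows, original columns
    predictions: np.ndarray  # model predictions for the explained rows
    background_size: int
    level: str = "feature"  # "feature" after estimation, "variable" after aggregation
    n_permutations: int = 0
    seed: int | None = None

    def check_additivity(self, rtol: float = 1e-6) -> None:
        recon = self.base_value + self.values.sum(axis=1).to_numpy()
        scale = np.maximum(np.abs(self.predictions), 1.0)
        if not np.all(np.abs(recon - self.predictions) <= rtol * scale):
            raise AssertionError("additivity violated: base + sum(values) != prediction")


def shapley_attributions(predict_fn, background: pd.DataFrame,
                         explain: pd.DataFrame, seed: int = 0,
                         n_permutations: int = 6) -> ShapReport:
    """Permutation-chain Shapley estimation.

    ``predict_fn`` maps a DataFrame of original design rows to a prediction
    vector.  For each explained row and each of ``n_permutations`` random
    feature orderings (drawn once and shared across rows; half are used
    reversed, the antithetic pairing that cancels first-order order noise),
    every background row is morphed feature-by-feature into the explained
    row and the mean prediction increment at each step is credited to the
    feature introduced there.
    """
    if len(background) == 0:
        raise ValueError("background must be non-empty")
    cols = list(background.columns)
    if list(explain.columns) != cols:
        explain = explain[cols]
    rng = np.random.default_rng(seed)
    n_feat = len(cols)
    bg = background.to_numpy(dtype=float)
    n_bg = len(bg)

    base_preds = np.asarray(predict_fn(background), dtype=float)
    if not np.isfinite(base_preds).all():
        raise ValueError("predict_fn returned non-finite values on the background")
    phi0 = float(base_preds.mean())

    half = max(1, n_permutations // 2)
    forward = [rng.permutation(n_feat) for _ in range(half)]
    perms = forward + [p[::-1] for p in forward[:n_permutations - half]]

    values = np.zeros((len(explain), n_feat))
    preds_out = np.empty(len(explain))
    for r, (_, row) in enumerate(explain.iterrows()):
        x = row.to_numpy(dtype=float)
        contrib = np.zeros(n_feat)
        for perm in perms:
            # stage s = background rows with features perm[:s] replaced by x
            stages = np.repeat(bg[None, :, :], n_feat + 1, axis=0)
            for s in range(1, n_feat + 1):
                stages[s:, :, perm[s - 1]] = x[perm[s - 1]]
            flat = stages.reshape(-1, n_feat)
            preds = np.asarray(
                predict_fn(pd.DataFrame(flat, columns=cols)), dtype=float)
            if not np.isfinite(preds).all():
                raise ValueError("predict_fn returned non-finite values")
            preds = preds.reshape(n_feat + 1, n_bg).mean(axis=1)
            contrib[perm] += np.diff(preds)
        values[r] = contrib / len(perms)
        preds_out[r] = float(
            np.asarray(predict_fn(explain.iloc[[r]]), dtype=float)[0])

    report = ShapReport(
        base_value=phi0,
        values=pd.DataFrame(values, index=explain.index, columns=cols),
        X_explain=explain.copy(), predictions=preds_out,
        background_size=n_bg, level="feature",
        n_permutations=len(perms), seed=seed)
    report.check_additivity()
    return report


def aggregate_variable_shap(report: ShapReport, groups: FeatureGroups) -> ShapReport:
    """Sum per-column attributions into per-variable attributions.

    A variable's value on a sample is the sum over its member columns
    (single-day lags plus cumulative lag features), so additivity is
    preserved exactly at the variable level.
    """
    if report.level != "feature":
        raise ValueError("report is already aggregated")
    unmapped = [c for c in report.values.columns
                if c not in groups.column_to_variable]
    if unmapped:
        raise KeyError(f"columns without a variable mapping: {unmapped}")
    var_of = groups.column_to_variable
    agg = report.values.T.groupby(
        report.values.columns.map(var_of)).sum().T
    # keep first-appearance variable order
    agg = agg[[v for v in groups.variables() if v in agg.columns]]
    return replace(report, values=agg, level="variable")


def global_importance(report: ShapReport) -> pd.DataFrame:
    """Mean absolute attribution per column/variable, ranked descending.

    Ties are broken alphabetically.
    """
    if len(report.values) == 0:
        raise ValueError("report covers no samples")
    imp = report.values.abs().mean(axis=0)
    table = (imp.rename("importance").rename_axis("variable").reset_index()
             .sort_values(["importance", "variable"],
                          ascending=[False, True], kind="mergesort")
             .reset_index(drop=True))
    return table


def three_part_decomposition(report: ShapReport,
                             groups: FeatureGroups) -> pd.DataFrame:
    """Split each prediction into base value + regular + volatile parts.

    *regular* sums the attributions of historical-admission and calendar
    variables; *volatile* sums the environmental ones.  The three parts
    reconstruct the prediction on every sample.
    """
    if report.level != "variable":
        report = aggregate_variable_shap(report, groups)
    unmapped = [v for v in report.values.columns if v not in groups.variable_to_part]
    if unmapped:
        raise KeyError(f"variables without a part mapping: {unmapped}")
    parts = report.values.columns.map(groups.variable_to_part)
    regular = report.values.loc[:, np.isin(parts, ("HAs", "calendar"))].sum(axis=1)
    volatile = report.values.loc[:, parts == "environmental"].sum(axis=1)
    out = pd.DataFrame({
        "base_value": report.base_value,
        "regular": regular, "volatile": volatile,
        "prediction": report.predictions,
    }, index=report.values.index)
    recon = out["base_value"] + out["regular"] + out["volatile"]
    scale = np.maximum(np.abs(out["prediction"]), 1.0)
    if not np.all(np.abs(recon - out["prediction"]) <= 1e-6 * scale):
        raise AssertionError("three-part decomposition does not reconstruct predictions")
    return out


def partial_prediction_metrics(decomposition: pd.DataFrame, y) -> pd.DataFrame:
    """Improvement attributable to the volatile (environmental) part.

    Evaluates the partial prediction (base value + regular part) and the full
    prediction with the four metrics and reports the per-metric relative
    improvement of full over partial.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(decomposition):
        raise ValueError("decomposition misaligned with observations")
    partial = (decomposition["base_value"] + decomposition["regular"]).to_numpy()
    full = decomposition["prediction"].to_numpy()
    rep_partial = compute_metrics(y, partial)
    rep_full = compute_metrics(y, full)
    rows = []
    for metric in ("MAE", "RMSE", "MAPE", "R2"):
        ref = rep_partial.as_dict()[metric]
        ach = rep_full.as_dict()[metric]
        direction = "increase" if metric == "R2" else "decrease"
        rows.append({"metric": metric, "partial": ref, "full": ach,
                     "improvement_pct": relative_improvement(ref, ach, direction)})
    return pd.DataFrame(rows).set_index("metric")


def local_waterfall(decomposition: pd.DataFrame, report: ShapReport,
                    groups: FeatureGroups, sample_ids) -> dict:
    """Per-sample waterfall from the regular baseline to the final prediction.

    The new baseline is base value + regular part; environmental variables
    are listed by decreasing |attribution| and their cumulative sum ends at
    the final prediction.
    """
    if report.level != "variable":
        report = aggregate_variable_shap(report, groups)
    env_vars = [v for v in report.values.columns
                if groups.variable_to_part[v] == "environmental"]
    out = {}
    for sid in sample_ids:
        if sid not in decomposition.index:
            raise KeyError(f"unknown sample id {sid!r}")
        row = decomposition.loc[sid]
        contribs = report.values.loc[sid, env_vars]
        ordered = contribs.reindex(
            contribs.abs().sort_values(ascending=False, kind="mergesort").index)
        out[sid] = {
            "new_baseline": float(row["base_value"] + row["regular"]),
            "contributions": [(v, float(ordered[v])) for v in ordered.index],
            "final_prediction": float(row["prediction"]),
        }
    return out


def dependence_export(report: ShapReport, feature: str) -> pd.DataFrame:
    """(feature value, attribution) pairs for a dependence plot; no smoothing."""
    if feature not in report.values.columns:
        raise KeyError(f"unknown feature {feature!r}")
    if feature in report.X_explain.columns:
        x = report.X_explain[feature]
    else:
        raise KeyError(f"feature {feature!r} has no stored input values")
    return pd.DataFrame({"feature_value": x,
                         "shap_value": report.values[feature]})
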