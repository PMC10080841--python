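"""Forecast evaluation: MAE, RMSE, MAPE, R², paired tests and improvements.

MAPE is reported as a fraction (0.145 means 14.5%).  Model comparisons use a
paired two-sided t-test on per-day loss vectors — absolute errors for MAE,
squared errors for RMSE, absolute-percentage errors for MAPE — since the
compared models share the same test days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvalReport",
    "compute_metrics",
    "paired_error_t_test",
    "relative_improvement",
    "comparison_table",
]

METRICS = ("MAE", "RMSE", "MAPE", "R2")
#: direction in which each metric improves
HIGHER_IS_BETTER = {"MAE": False, "RMSE": False, "MAPE": False, "R2": True}


@dataclass
class EvalReport:
    mae: float
    rmse: float
    mape: float
    r2: float
    n: int
    abs_errors: np.ndarray | None = None
    sq_errors: np.ndarray | None = None
    ape_errors: np.ndarray | None = None

    def as_dict(self) -> dict[str, float]:
        return {"MAE": self.mae, "RMSE": self.rmse,
                "MAPE": self.mape, "R2": self.r2}


def compute_metrics(y, yhat, epsilon: float | None = None,
                    keep_errors: bool = True) -> EvalReport:
    """The four standard point-forecast metrics.

    MAE = mean|y-ŷ|, RMSE = sqrt(mean (y-ŷ)²), MAPE = mean(|y-ŷ|/y) as a
    fraction, R² = 1 - SSE/SST.  Observations must be positive for MAPE
    unless an ``epsilon`` guard is supplied (denominator max(y, epsilon)).
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    if y.size < 2:
        raise ValueError("need at least two observations")
    if epsilon is None and np.any(y <= 0):
        raise ValueError("non-positive observation; MAPE undefined "
                         "(configure an epsilon guard)")
    resid = y - yhat
    abs_err = np.abs(resid)
    sq_err = resid ** 2
    denom = y if epsilon is None else np.maximum(y, epsilon)
    ape = abs_err / denom
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(sq_err) / sst if sst > 0 else (1.0 if np.allclose(resid, 0) else -np.inf)
    return EvalReport(
        mae=float(abs_err.mean()), rmse=float(np.sqrt(sq_err.mean())),
        mape=float(ape.mean()), r2=float(r2), n=int(y.size),
        abs_errors=abs_err if keep_errors else None,
        sq_errors=sq_err if keep_errors else None,
        ape_errors=ape if keep_errors else None)


def paired_error_t_test(errors_a, errors_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-day loss vectors.

    Returns ``(t, p)``.  Degenerate cases: identical vectors give (0, 1);
    a zero-variance nonzero difference gives p = 0 with a warning.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("error vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least three paired losses")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        warnings.warn("zero-variance nonzero difference; p reported as 0")
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), df=d.size - 1)
    return float(t), float(p)


def relative_improvement(reference: float, achieved: float,
                         direction: str = "decrease") -> float:
    """Percent change of ``achieved`` relative to ``reference``.

    ``decrease``: 100*(reference - achieved)/reference (error metrics);
    ``increase``: 100*(achieved - reference)/reference (R²).
    """
    if reference == 0:
        raise ValueError("reference must be nonzero")
    if direction == "decrease":
        return 100.0 * (reference - achieved) / reference
    if direction == "increase":
        return 100.0 * (achieved - reference) / reference
    raise ValueError("direction must be 'decrease' or 'increase'")


def comparison_table(models: dict[str, np.ndarray], y,
                     reference_models: list[str] | None = None,
                     alpha: float = 0.05,
                     epsilon: float | None = None) -> pd.DataFrame:
    """One row per model with the four metrics, best-per-metric flags and
    significance stars.

    ``reference_models`` names the individual (non-ensemble) models; every
    other model is tested against the per-metric best reference model with a
    paired t-test on the matching loss vector, and starred when p < alpha.
    With no reference set, no stars are computed.
    """
    if not models:
        raise ValueError("empty model set")
    y = np.asarray(y, dtype=float)
    reports = {}
    for name, yhat in models.items():
        yhat = np.asarray(yhat, dtype=float)
        if yhat.shape != y.shape:
            raise ValueError(f"predictions for {name!r} misaligned with y")
        reports[name] = compute_metrics(y, yhat, epsilon=epsilon)

    rows = []
    ref = [m for m in (reference_models or []) if m in reports]
    loss_attr = {"MAE": "abs_errors", "RMSE": "sq_errors", "MAPE": "ape_errors"}
    for name, rep in reports.items():
        row = {"model": name, **rep.as_dict()}
        for metric in ("MAE", "RMSE", "MAPE"):
            star = ""
            if ref and name not in ref:
                vals = {r: getattr(reports[r], "as_dict")()[metric] for r in ref}
                best_ref = min(vals, key=vals.get)
                _, p = paired_error_t_test(
                    getattr(reports[best_ref], loss_attr[metric]),
                    getattr(rep, loss_attr[metric]))
                if p < alpha:
                    star = "*"
            row[f"{metric}_sig"] = star
        rows.append(row)
    table = pd.DataFrame(rows).set_index("model")
    for metric in METRICS:
        col = table[metric]
        best = col.idxmax() if HIGHER_IS_BETTER[metric] else col.idxmin()
        table[f"{metric}_best"] = table.index == best
    return table
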