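"""From a daily panel to the supervised design: lags, calendar, scaling, split.

The design follows standard practice in short-term environmental epidemiology:
the predictors for day *t* are the admission counts and environmental values
on days *t-1 .. t-L* (single-day lags plus the moving mean/SD over the window,
L = 6 by default), together with calendar features (day of week, month,
season, year, serial timestamp, holiday/workday indicators).  Categorical
calendar codes are one-hot expanded and continuous columns min–max scaled,
with every fitted statistic (category sets, min/max) estimated on the
chronological training block only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .synthetic import ENV_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "DISPLAY_NAMES",
    "LagSpec",
    "FeatureMatrix",
    "SplitDatasets",
    "interpolate_missing",
    "make_lag_features",
    "make_calendar_features",
    "build_feature_matrix",
    "one_hot_expand",
    "minmax_scale",
    "chronological_split",
    "prepare_datasets",
]

#: canonical panel column -> display name used in feature-column labels
DISPLAY_NAMES = {
    "ha_count": "HAs", "pm25": "PM2.5", "pm10": "PM10", "pmc": "PMc",
    "so2": "SO2", "no2": "NO2", "co": "CO", "o3": "O3", "aqi": "AQI",
    "tem": "TEM", "rh": "RH",
}

ONE_HOT_COLUMNS = ("DOW", "MON", "SEA", "YEAR")
CALENDAR_BINARY = ("HOL", "WD", "FWD", "LWD")


@dataclass(frozen=True)
class LagSpec:
    """Maximum lag L; single-day lags 1..L plus cumulative mean/SD over [1, L]."""

    L: int = 6

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("L must be >= 1")

    @property
    def single_day_lags(self) -> range:
        return range(1, self.L + 1)


@dataclass
class FeatureMatrix:
    """A named design matrix with per-column group tags and the target."""

    X: pd.DataFrame
    y: pd.Series
    groups: dict[str, str]  # column -> {"HAs", "environmental", "calendar", "meta"}
    norm_records: dict[str, tuple[float, float]] = field(default_factory=dict)
    onehot_categories: dict[str, list[int]] = field(default_factory=dict)


@dataclass
class SplitDatasets:
    """Chronological train/test split of a feature matrix."""

    X_train: pd.DataFrame
    y_train: pd.Series
    X_test: pd.DataFrame
    y_test: pd.Series
    split_date: pd.Timestamp
    groups: dict[str, str]
    norm_records: dict[str, tuple[float, float]]
    onehot_categories: dict[str, list[int]]


def interpolate_missing(panel: pd.DataFrame) -> pd.DataFrame:
    """Fill missing environmental cells by linear interpolation in time.

    Interior gaps are interpolated between the nearest non-missing neighbours;
    leading/trailing runs are filled by nearest-value extension (a straight
    line needs two anchors).  ``ha_count`` is never touched.
    """
    panel = panel.copy()
    for col in ENV_COLUMNS:
        if col not in panel.columns:
            continue
        s = panel[col]
        if s.isna().all():
            raise ValueError(f"column {col!r} is entirely missing")
        panel[col] = s.interpolate(method="linear", limit_direction="both")
    return panel


def make_lag_features(panel: pd.DataFrame, spec: LagSpec) -> FeatureMatrix:
    """Lagged predictors for the target and each environmental series.

    For series ``S`` with display name ``name``: columns ``name Lag x``
    (x = 1..L), ``name Lag 1L mean`` and ``name Lag 1L std`` (sample SD over
    the L single-day lags).  The first L rows lack full history and are
    dropped rather than padded.
    """
    L = spec.L
    if len(panel) < L + 1:
        raise ValueError(f"panel needs at least L+1={L + 1} rows")
    env_present = [c for c in ENV_COLUMNS if c in panel.columns]
    if panel[env_present].isna().any().any():
        raise ValueError("environmental columns contain missing values; interpolate first")

    dates = pd.to_datetime(panel["date"])
    frames: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for col in ["ha_count"] + env_present:
        name = DISPLAY_NAMES[col]
        series = panel[col].to_numpy(dtype=float)
        lag_block = np.column_stack(
            [np.roll(series, x) for x in spec.single_day_lags])
        group = "HAs" if col == "ha_count" else "environmental"
        for i, x in enumerate(spec.single_day_lags):
            frames[f"{name} Lag {x}"] = lag_block[:, i]
            groups[f"{name} Lag {x}"] = group
        frames[f"{name} Lag 1L mean"] = lag_block.mean(axis=1)
        frames[f"{name} Lag 1L std"] = lag_block.std(axis=1, ddof=1)
        groups[f"{name} Lag 1L mean"] = group
        groups[f"{name} Lag 1L std"] = group

    X = pd.DataFrame(frames, index=dates).iloc[L:]
    y = pd.Series(panel["ha_count"].to_numpy()[L:], index=X.index, name="HAs")
    return FeatureMatrix(X=X, y=y, groups=groups)


def make_calendar_features(dates: pd.DatetimeIndex,
                           holidays: frozenset[date] | set[date]) -> FeatureMatrix:
    """Calendar features for consecutive dates.

    DOW 1–7 (Monday=1), MON 1–12, SEA (meteorological seasons: Mar–May=1
    spring, Jun–Aug=2, Sep–Nov=3, Dec–Feb=4), YEAR (ordinal from the first
    year), TS (serial 1..n), and binary HOL, WD (workday = not weekend, not
    holiday), FWD/LWD (first/last workday of each contiguous workday run).
    """
    dates = pd.DatetimeIndex(dates)
    if len(dates) > 1 and not (np.diff(dates.to_numpy()).astype("timedelta64[D]")
                               == np.timedelta64(1, "D")).all():
        raise ValueError("dates must be consecutive calendar days")

    dow = dates.dayofweek.to_numpy() + 1  # Monday=1
    mon = dates.month.to_numpy()
    sea = np.select(
        [np.isin(mon, (3, 4, 5)), np.isin(mon, (6, 7, 8)), np.isin(mon, (9, 10, 11))],
        [1, 2, 3], default=4)
    year = dates.year.to_numpy() - dates[0].year + 1
    ts = np.arange(1, len(dates) + 1)
    hol = np.array([d.date() in holidays for d in dates], dtype=int)
    wd = ((dow <= 5) & (hol == 0)).astype(int)
    # first/last workday of each contiguous workday run
    prev_wd = np.concatenate([[0], wd[:-1]])
    next_wd = np.concatenate([wd[1:], [0]])
    fwd = ((wd == 1) & (prev_wd == 0)).astype(int)
    lwd = ((wd == 1) & (next_wd == 0)).astype(int)

    X = pd.DataFrame(
        {"DOW": dow, "MON": mon, "SEA": sea, "YEAR": year, "TS": ts,
         "HOL": hol, "WD": wd, "FWD": fwd, "LWD": lwd},
        index=dates)
    groups = {c: "calendar" for c in X.columns}
    return FeatureMatrix(X=X, y=pd.Series(dtype=float), groups=groups)


def build_feature_matrix(panel: pd.DataFrame, spec: LagSpec,
                         holidays: frozenset[date] | set[date]) -> FeatureMatrix:
    """Assemble the full raw design: lag block then calendar block."""
    lagged = make_lag_features(panel, spec)
    cal = make_calendar_features(lagged.X.index, holidays)
    X = pd.concat([lagged.X, cal.X], axis=1)
    groups = {**lagged.groups, **cal.groups}
    return FeatureMatrix(X=X, y=lagged.y, groups=groups)


def one_hot_expand(features: pd.DataFrame,
                   columns: tuple[str, ...] = ONE_HOT_COLUMNS,
                   categories: dict[str, list[int]] | None = None,
                   ) -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Replace integer-coded columns by one indicator per category.

    The full encoding is kept (no dropped category).  When ``categories`` is
    given (fitted on training rows) it is reused; values outside the fitted
    set yield all-zero indicators and a logged warning.
    """
    out = features.copy()
    fitted: dict[str, list[int]] = {}
    for col in columns:
        if col not in out.columns:
            raise KeyError(f"column {col!r} not present")
        if categories is None:
            cats = sorted(out[col].unique().tolist())
        else:
            cats = categories[col]
            unseen = set(out[col].unique()) - set(cats)
            if unseen:
                logger.warning(
                    "column %s: categories %s unseen in training; "
                    "encoded as all-zero indicators", col, sorted(unseen))
        fitted[col] = list(cats)
        pos = out.columns.get_loc(col)
        indicators = {f"{col}_{c}": (out[col] == c).astype(float) for c in cats}
        left = out.iloc[:, :pos]
        right = out.iloc[:, pos + 1:]
        out = pd.concat([left, pd.DataFrame(indicators, index=out.index), right],
                        axis=1)
    return out, fitted


def minmax_scale(train_column: pd.Series, test_column: pd.Series | None = None,
                 ) -> tuple[pd.Series, pd.Series | None, tuple[float, float]]:
    """Min–max scale, X' = (X - min) / (max - min), with train-only statistics.

    Test values may fall outside [0, 1]; no clipping.  A constant training
    column scales to all-zeros with a logged warning.
    """
    lo, hi = float(train_column.min()), float(train_column.max())
    if hi == lo:
        logger.warning("constant training column %r scaled to zeros",
                       train_column.name)
        scaled_train = train_column * 0.0
        scaled_test = None if test_column is None else test_column * 0.0
        return scaled_train, scaled_test, (lo, hi)
    scaled_train = (train_column - lo) / (hi - lo)
    scaled_test = None if test_column is None else (test_column - lo) / (hi - lo)
    return scaled_train, scaled_test, (lo, hi)


def chronological_split(features: FeatureMatrix, split_date,
                        normalize: bool = True) -> SplitDatasets:
    """Split by date, then fit one-hot categories and min–max records on the
    training block only and apply them to both blocks.

    Lag features are computed on the full panel before splitting, so test
    rows keep their true history; no training-fitted statistic sees test rows.
    """
    split_date = pd.Timestamp(split_date)
    idx = features.X.index
    if not (idx.min() < split_date <= idx.max()):
        raise ValueError(f"split_date {split_date.date()} outside the feature range")
    train_mask = idx < split_date
    if not train_mask.any():
        raise ValueError("empty training set")

    X_train_raw = features.X.loc[train_mask]
    X_test_raw = features.X.loc[~train_mask]
    one_hot_cols = tuple(c for c in ONE_HOT_COLUMNS if c in features.X.columns)
    X_train, cats = one_hot_expand(X_train_raw, one_hot_cols)
    X_test, _ = one_hot_expand(X_test_raw, one_hot_cols, categories=cats)
    X_test = X_test.reindex(columns=X_train.columns, fill_value=0.0)

    groups = dict(features.groups)
    for col, cat_list in cats.items():
        g = groups.pop(col)
        for c in cat_list:
            groups[f"{col}_{c}"] = g

    indicator_cols = {f"{c}_{v}" for c, vs in cats.items() for v in vs}
    indicator_cols |= {c for c in CALENDAR_BINARY if c in X_train.columns}
    norm_records: dict[str, tuple[float, float]] = {}
    if normalize:
        for col in X_train.columns:
            if col in indicator_cols:
                continue
            tr, te, rec = minmax_scale(X_train[col], X_test[col])
            X_train[col], X_test[col] = tr, te
            norm_records[col] = rec

    return SplitDatasets(
        X_train=X_train, y_train=features.y.loc[train_mask],
        X_test=X_test, y_test=features.y.loc[~train_mask],
        split_date=split_date, groups=groups,
        norm_records=norm_records, onehot_categories=cats)


def prepare_datasets(panel: pd.DataFrame, spec: LagSpec,
                     holidays: frozenset[date] | set[date], split_date,
                     normalize: bool = True) -> SplitDatasets:
    """Full preprocessing: interpolate, build the design, split and scale."""
    panel = interpolate_missing(panel)
    features = build_feature_matrix(panel, spec, holidays)
    return chronological_split(features, split_date, normalize=normalize)
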