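"""Round-trippable file formats for panels, designs, weights and reports.

The panel CSV dialect: header ``date,ha_count,pm25,pm10,pmc,so2,no2,co,o3,
aqi,tem,rh``, ISO-8601 dates, an empty field meaning missing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import SplitDatasets
from .synthetic import ENV_COLUMNS, PANEL_COLUMNS

__all__ = ["load_panel_csv", "write_panel_csv", "write_design", "load_design"]


def load_panel_csv(path) -> pd.DataFrame:
    """Read a daily panel, validating the dialect row by row."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != PANEL_COLUMNS:
        raise ValueError(
            f"{path.name}: header must be {','.join(PANEL_COLUMNS)}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    except ValueError as exc:
        raise ValueError(f"{path.name}: unparseable ISO-8601 date: {exc}") from exc
    if df["ha_count"].isna().any():
        row = int(df["ha_count"].isna().idxmax()) + 2  # header is line 1
        raise ValueError(f"{path.name}, line {row}: ha_count is missing")
    bad = df.index[df["ha_count"] < 0]
    if len(bad):
        raise ValueError(f"{path.name}, line {int(bad[0]) + 2}: negative ha_count")
    df["ha_count"] = df["ha_count"].astype(np.int64)
    for col in ENV_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def write_panel_csv(panel: pd.DataFrame, path) -> None:
    out = panel.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep="")


def write_design(split: SplitDatasets, directory) -> None:
    """Design matrix as CSV plus a JSON sidecar of fitted statistics."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for part, X, y in (("train", split.X_train, split.y_train),
                       ("test", split.X_test, split.y_test)):
        frame = X.copy()
        frame.insert(0, "Y", y)
        frame.to_csv(directory / f"design_{part}.csv",
                     index_label="date", date_format="%Y-%m-%d")
    sidecar = {
        "split_date": str(split.split_date.date()),
        "groups": split.groups,
        "norm_records": {k: list(v) for k, v in split.norm_records.items()},
        "onehot_categories": {k: [int(c) for c in v]
                              for k, v in split.onehot_categories.items()},
    }
    (directory / "design_meta.json").write_text(json.dumps(sidecar, indent=2))


def load_design(directory) -> SplitDatasets:
    directory = Path(directory)
    meta = json.loads((directory / "design_meta.json").read_text())
    parts = {}
    for part in ("train", "test"):
        frame = pd.read_csv(directory / f"design_{part}.csv",
                            index_col="date", parse_dates=["date"])
        parts[part] = (frame.drop(columns=["Y"]), frame["Y"])
    return SplitDatasets(
        X_train=parts["train"][0], y_train=parts["train"][1],
        X_test=parts["test"][0], y_test=parts["test"][1],
        split_date=pd.Timestamp(meta["split_date"]),
        groups=meta["groups"],
        norm_records={k: tuple(v) for k, v in meta["norm_records"].items()},
        onehot_categories=meta["onehot_categories"])
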