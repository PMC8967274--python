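"""CSV/JSON plumbing with strict schema checks.

Experiment and climate tables are UTF-8 CSV with a header row and "." decimal
separator; temperatures are degrees Celsius and the day/night regime is
stored as two columns. Schema errors name the offending column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .preprocess import RECORD_COLUMNS

CLIMATE_COLUMNS = ("population_id", "range_label", "latitude", "mat", "seasonality")
RANGE_LABELS = ("native", "invasive")


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} is missing required column {col!r}")


def _fold_range_label(df: pd.DataFrame, what: str) -> pd.DataFrame:
    folded = df["range_label"].astype(str).str.strip().str.lower()
    bad = ~folded.isin(RANGE_LABELS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{what} row {row}: unknown range_label "
            f"{df['range_label'].iloc[row]!r} (expected one of {RANGE_LABELS})"
        )
    df = df.copy()
    df["range_label"] = folded
    return df


def _coerce_numeric(df: pd.DataFrame, columns, what: str) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{what} row {row}: column {col!r} has non-numeric value "
                f"{df[col].iloc[row]!r}"
            )
        df[col] = coerced
    return df


def read_experiment_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, RECORD_COLUMNS, "experiment table")
    df = _fold_range_label(df, "experiment table")
    df = _coerce_numeric(
        df, ("day_temp", "night_temp", "stem_in", "stem_out", "days"), "experiment table"
    )
    if (df["days"].dropna() <= 0).any():
        raise SchemaError("experiment table: column 'days' must be a positive count")
    df["established"] = df["established"].astype(bool)
    df["damaged"] = df["damaged"].astype(bool)
    return df


def read_climate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, CLIMATE_COLUMNS, "climate table")
    df = _fold_range_label(df, "climate table")
    df = _coerce_numeric(df, ("latitude", "mat", "seasonality"), "climate table")
    if df["population_id"].duplicated().any():
        dup = df.loc[df["population_id"].duplicated(), "population_id"].iloc[0]
        raise SchemaError(f"climate table: duplicate population_id {dup!r}")
    if (df["seasonality"] < 0).any():
        raise SchemaError("climate table: 'seasonality' must be >= 0")
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
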