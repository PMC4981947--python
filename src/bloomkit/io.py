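"""CSV/JSON/YAML I/O for lake time series and run configuration.

One CSV per lake, one row per sampling occasion. The date column may be
ISO-8601 dates or integer day offsets; internally everything is integer
day offsets (calendar only at I/O). Missing values are preserved as
missing, never imputed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import LakeMeta, PlanktonTimeSeries

__all__ = [
    "TimeSeriesFormatError",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "write_ground_truth",
    "file_sha256",
]


class TimeSeriesFormatError(ValueError):
    pass


def _to_day_index(col: pd.Series) -> pd.Series:
    if pd.api.types.is_numeric_dtype(col):
        return col.astype(float)
    try:
        dates = pd.to_datetime(col, format="ISO8601")
    except (ValueError, TypeError) as e:
        raise TimeSeriesFormatError(
            f"date column must be ISO-8601 or numeric day offsets: {e}"
        ) from e
    return (dates - dates.iloc[0]).dt.total_seconds() / 86400.0


def read_timeseries_csv(path: str | Path, lake_id: str | None = None,
                        ) -> PlanktonTimeSeries:
    """Load and validate one lake's time series.

    Requires a ``day`` or ``date`` column, strictly increasing with no
    duplicates. Missing cells load as NaN with their missingness intact.
    """
    path = Path(path)
    df = pd.read_csv(path)
    time_col = "day" if "day" in df.columns else (
        "date" if "date" in df.columns else None)
    if time_col is None:
        raise TimeSeriesFormatError("need a 'day' or 'date' column")
    day = _to_day_index(df[time_col])
    if day.duplicated().any():
        raise TimeSeriesFormatError("duplicate timestamps")
    if not day.is_monotonic_increasing:
        raise TimeSeriesFormatError("timestamps must be strictly increasing")
    df = df.copy()
    df["day"] = day
    lid = lake_id or (str(df["lake_id"].iloc[0]) if "lake_id" in df.columns
                      else path.stem)
    return PlanktonTimeSeries(lake_id=lid, data=df)


def write_timeseries_csv(ts: PlanktonTimeSeries, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ts.data.assign(lake_id=ts.lake_id).to_csv(path, index=False)
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_ground_truth(truth, path: str | Path) -> Path:
    """Serialize a GroundTruth ledger to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = []
    for lake in truth.lakes:
        d = asdict(lake)
        payload.append(_jsonable(d))
    path.write_text(json.dumps(payload, indent=1))
    return path


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise TimeSeriesFormatError("config YAML must be a mapping")
    return cfg
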