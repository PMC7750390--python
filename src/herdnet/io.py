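"""Delimited-text readers and writers for all pipeline artifacts.

Position tables are CSV with columns animal_id, day_index, timestamp,
x_m, y_m; timestamps are epoch seconds internally, ISO-8601 accepted on
input.  Interaction matrices are square CSV with animal-id header row and
column and empty diagonal cells.  All writers are deterministic (no wall
clock, fixed float formatting) so reruns are byte-identical.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import POSITION_COLUMNS

FLOAT_FMT = "%.6f"


def write_positions(positions: pd.DataFrame, path) -> None:
    positions[POSITION_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FMT)


def read_positions(path) -> pd.DataFrame:
    """Read a position table, reporting malformed rows by line number."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty file, returning empty table", stacklevel=2)
        return pd.DataFrame(columns=POSITION_COLUMNS)
    missing = [c for c in POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        warnings.warn(f"{path}: no records", stacklevel=2)
        return df[POSITION_COLUMNS]
    ts = df["timestamp"]
    if ts.dtype == object:
        numeric = pd.to_numeric(ts, errors="coerce")
        need_iso = numeric.isna() & ts.notna()
        if need_iso.any():
            parsed = pd.to_datetime(ts[need_iso], errors="coerce", utc=True)
            secs = parsed.astype("int64").astype(float) / 1e9
            secs[parsed.isna()] = np.nan
            numeric = numeric.copy()
            numeric[need_iso] = secs
        df["timestamp"] = numeric
    for col in ("day_index", "timestamp", "x_m", "y_m"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2
            raise ValueError(f"{path}: missing value in column {col!r} at line {line}")
        df[col] = vals
    df["day_index"] = df["day_index"].astype(int)
    return df[POSITION_COLUMNS]


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, float_format=FLOAT_FMT, na_rep="")


def read_matrix(path) -> pd.DataFrame:
    m = pd.read_csv(path, index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    if m.shape[0] != m.shape[1] or not (m.index == m.columns).all():
        raise ValueError(f"{path}: not a square id-labelled matrix")
    return m


def write_edge_list(matrix: pd.DataFrame, day_index: int, zone: str, path) -> None:
    """Long-format dyadic counts: day, zone, id_a, id_b, count."""
    ids = list(matrix.index)
    v = matrix.to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(ids), 1)
    df = pd.DataFrame(
        {
            "day_index": day_index,
            "zone": zone,
            "id_a": [ids[i] for i in iu],
            "id_b": [ids[j] for j in ju],
            "count": v[iu, ju],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_attributes(attributes: pd.DataFrame, path) -> None:
    attributes.to_csv(path, index=False)


def read_attributes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth_intervals(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_truth_intervals(path) -> pd.DataFrame:
    return pd.read_csv(path)
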