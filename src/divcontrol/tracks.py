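"""Track tables: per-cell length time series with genealogy.

The canonical on-disk dialect is a UTF-8 CSV with header
``cell_id,parent_id,time_min,length_um`` ('.' decimal separator); parent_id is
empty for root cells.  Extra columns (e.g. a width column) are tolerated and
preserved.  In memory a track table is a plain pandas DataFrame with those
columns, ``parent_id`` held as a nullable integer.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["COLUMNS", "validate_tracks", "read_tracks", "write_tracks"]

COLUMNS = ["cell_id", "parent_id", "time_min", "length_um"]


class TrackValidationError(ValueError):
    """Raised when a track table violates the schema contract."""


def _as_track_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrackValidationError(f"missing required columns: {missing}")
    out = df.copy()
    out["cell_id"] = out["cell_id"].astype("int64")
    out["parent_id"] = out["parent_id"].astype("Int64")
    out["time_min"] = out["time_min"].astype(float)
    out["length_um"] = out["length_um"].astype(float)
    return out


def validate_tracks(df: pd.DataFrame, rtol_spacing: float = 1e-6) -> pd.DataFrame:
    """Validate genealogy and per-cell time grids; return the coerced table.

    Checks, with row/cell references in the error message:
    * required columns, positive lengths, non-negative times;
    * per cell: strictly increasing times with constant spacing;
    * every non-null parent_id refers to a cell present in the table whose
      last observation precedes the child's first observation.
    """
    df = _as_track_frame(df)
    if len(df) == 0:
        raise TrackValidationError("empty track table")
    bad = df.index[~np.isfinite(df["length_um"]) | (df["length_um"] <= 0)]
    if len(bad):
        raise TrackValidationError(
            f"non-positive or non-finite length at rows {list(bad[:5])}")
    if (df["time_min"] < 0).any():
        rows = df.index[df["time_min"] < 0]
        raise TrackValidationError(f"negative time at rows {list(rows[:5])}")

    df = df.sort_values(["cell_id", "time_min"], kind="mergesort",
                        ignore_index=True)
    g = df.groupby("cell_id", sort=True)
    diffs = g["time_min"].diff().dropna()
    if (diffs <= 0).any():
        cell = df.loc[diffs.index[diffs <= 0][0], "cell_id"]
        raise TrackValidationError(
            f"times not strictly increasing within cell {cell}")
    spacing = g["time_min"].agg(lambda t: np.ptp(np.diff(t)) if len(t) > 2 else 0.0)
    step = g["time_min"].agg(lambda t: np.diff(t).min() if len(t) > 1 else np.nan)
    ref = np.nanmedian(step.to_numpy(dtype=float))
    if np.isfinite(ref) and ref > 0:
        irregular = spacing[spacing > rtol_spacing * ref * 10]
        if len(irregular):
            raise TrackValidationError(
                f"non-constant acquisition spacing within cell "
                f"{irregular.index[0]}")

    first = g["time_min"].min()
    last = g["time_min"].max()
    parents = df.loc[df["parent_id"].notna(), ["cell_id", "parent_id"]]
    parents = parents.drop_duplicates("cell_id")
    pids = parents["parent_id"].astype("int64")
    parent_last = pids.map(last)
    dangling = parents.loc[parent_last.isna(), "cell_id"]
    if len(dangling):
        cid = dangling.iloc[0]
        pid = int(parents.set_index("cell_id").loc[cid, "parent_id"])
        raise TrackValidationError(f"cell {cid} references missing parent {pid}")
    child_first = parents["cell_id"].map(first)
    early = parents[parent_last.to_numpy() > child_first.to_numpy()]
    if len(early):
        cid = early["cell_id"].iloc[0]
        pid = int(early["parent_id"].iloc[0])
        raise TrackValidationError(
            f"cell {cid} starts at t={first[cid]} before the last frame "
            f"t={last[pid]} of its parent {pid}")
    return df


def read_tracks(path) -> pd.DataFrame:
    """Read and validate a track table CSV (tolerant of extra columns)."""
    df = pd.read_csv(path)
    return validate_tracks(df)


def write_tracks(df: pd.DataFrame, path) -> None:
    """Write a track table in the canonical CSV dialect (parent empty for roots)."""
    out = df.copy()
    out["parent_id"] = out["parent_id"].astype("Int64")
    out.to_csv(path, index=False)
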