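"""Per-cell cycle summaries extracted from track tables.

A *cell cycle* runs from an observed birth (the cell's first frame, which for
a cell with a recorded parent is the division frame of that parent) to an
observed division (the cell's last frame, when at least one daughter appears
in the table).  Cells whose birth or division falls outside the observation
window are flagged ``complete=False`` and excluded from rate estimation.

CSV dialect: ``cell_id,birth_time_min,birth_size_um,division_time_min,
division_size_um,division_age_min,growth_rate_per_min,septum_ratio,complete``
(a ``generation`` column is carried additionally).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["extract_cycles", "occupation_measure", "CYCLE_COLUMNS"]

CYCLE_COLUMNS = ["cell_id", "birth_time_min", "birth_size_um",
                 "division_time_min", "division_size_um", "division_age_min",
                 "growth_rate_per_min", "septum_ratio", "complete"]


def _generations(cycles: pd.DataFrame) -> np.ndarray:
    """Depth of each cell in the genealogy (roots are generation 0)."""
    gen = {}
    out = np.zeros(len(cycles), dtype=int)
    order = np.argsort(cycles["birth_time_min"].to_numpy(), kind="mergesort")
    cid = cycles["cell_id"].to_numpy()
    pid = cycles["parent_id"].to_numpy()
    for i in order:
        p = pid[i]
        g = gen.get(p, -1) + 1 if not pd.isna(p) else 0
        gen[cid[i]] = g
        out[i] = g
    return out


def extract_cycles(tracks: pd.DataFrame,
                   discard_before: float = 0.0,
                   generation_window: tuple | None = None,
                   min_growth_points: int = 3) -> pd.DataFrame:
    """Summarize each cell of a track table into one CellCycle row.

    Parameters
    ----------
    tracks : validated track table (``cell_id,parent_id,time_min,length_um``).
    discard_before : drop cycles whose division happens before this time
        (min), used to skip the non-steady-state start of a full-tree
        experiment (e.g. the first 150 min).
    generation_window : ``(lo, hi)`` keeps generations lo < g <= hi, used for
        mother-machine data to exclude early transients and replicative
        aging.
    min_growth_points : minimum frames for the per-cell exponential growth
        fit; cells with fewer get NaN as growth rate.

    The per-cell growth rate is the slope of an ordinary least-squares fit of
    log-length against time.  The septum ratio of a cell is its birth length
    divided by its parent's division length.
    """
    df = tracks.sort_values(["cell_id", "time_min"], kind="mergesort")
    g = df.groupby("cell_id", sort=True)
    first = g.first()
    last = g.last()
    n_pts = g.size()

    # vectorized per-cell log-OLS slope
    t = df["time_min"].to_numpy()
    y = np.log(df["length_um"].to_numpy())
    tmp = pd.DataFrame({
        "cell_id": df["cell_id"].to_numpy(),
        "t": t, "y": y, "ty": t * y, "tt": t * t,
    })
    s = tmp.groupby("cell_id", sort=True).sum()
    n = n_pts.to_numpy(dtype=float)
    var_t = s["tt"].to_numpy() - s["t"].to_numpy() ** 2 / n
    cov_ty = s["ty"].to_numpy() - s["t"].to_numpy() * s["y"].to_numpy() / n
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(var_t > 0, cov_ty / np.maximum(var_t, 1e-300), np.nan)
    slope = np.where(n >= min_growth_points, slope, np.nan)

    cells = pd.DataFrame({
        "cell_id": first.index.to_numpy(),
        "parent_id": first["parent_id"].to_numpy(),
        "birth_time_min": first["time_min"].to_numpy(),
        "birth_size_um": first["length_um"].to_numpy(),
        "last_time_min": last["time_min"].to_numpy(),
        "last_size_um": last["length_um"].to_numpy(),
        "n_points": n_pts.to_numpy(),
        "growth_rate_per_min": slope,
    })
    has_child = cells["cell_id"].isin(
        set(cells.loc[pd.notna(cells["parent_id"]), "parent_id"].astype(int)))
    parent_observed = pd.notna(cells["parent_id"])
    cells["complete"] = (has_child & parent_observed).to_numpy()
    cells["division_time_min"] = np.where(has_child, cells["last_time_min"],
                                          np.nan)
    cells["division_size_um"] = np.where(has_child, cells["last_size_um"],
                                         np.nan)
    cells["division_age_min"] = (cells["division_time_min"]
                                 - cells["birth_time_min"])
    div_size = cells.set_index("cell_id")["division_size_um"]
    psize = cells["parent_id"].map(div_size)
    cells["septum_ratio"] = cells["birth_size_um"] / psize
    cells["generation"] = _generations(cells)

    keep = np.ones(len(cells), dtype=bool)
    if discard_before > 0:
        keep &= (np.nan_to_num(cells["division_time_min"].to_numpy(),
                               nan=np.inf) >= discard_before)
        keep &= cells["last_time_min"].to_numpy() >= discard_before
    if generation_window is not None:
        lo, hi = generation_window
        gens = cells["generation"].to_numpy()
        keep &= (gens > lo) & (gens <= hi)
    out = cells.loc[keep, ["cell_id", "parent_id", "generation",
                           "birth_time_min", "birth_size_um",
                           "division_time_min", "division_size_um",
                           "division_age_min", "growth_rate_per_min",
                           "septum_ratio", "complete"]].reset_index(drop=True)
    if not out["division_time_min"].notna().any():
        raise ValueError("no usable cycles: table contains no observed "
                         "division")
    return out


def occupation_measure(tracks: pd.DataFrame, cycles: pd.DataFrame,
                       discard_before: float = 0.0) -> pd.DataFrame:
    """(age, size) of every retained cell at every observation snapshot.

    The kernel density estimate of this point cloud is the empirical age-size
    distribution.  Only cells with an observed birth (a recorded parent) and
    present in ``cycles`` enter; age is time since the cell's first frame.
    A dividing cell's final frame is excluded: at that instant the daughters
    (age 0, same timestamp) have replaced the mother in the population, so
    keeping both would double-count the division event.  Observed ages live
    on the acquisition lattice and stand for the age interval up to the next
    frame; density estimation should therefore spread each atom forward by
    one frame (a one-frame boxcar after a half-frame shift).
    """
    info = cycles.loc[pd.notna(cycles["parent_id"]),
                      ["cell_id", "birth_time_min", "division_time_min",
                       "complete"]]
    merged = tracks.merge(info, on="cell_id", how="inner")
    is_div_frame = (merged["complete"].to_numpy()
                    & (merged["time_min"].to_numpy()
                       >= merged["division_time_min"].to_numpy() - 1e-9))
    merged = merged[~is_div_frame]
    if discard_before > 0:
        merged = merged[merged["time_min"] >= discard_before]
    age = merged["time_min"].to_numpy() - merged["birth_time_min"].to_numpy()
    return pd.DataFrame({"age_min": age,
                         "size_um": merged["length_um"].to_numpy()})
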