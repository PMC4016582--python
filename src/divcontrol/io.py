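"""File formats and run configuration.

Units are minutes and micrometres everywhere.  CSV dialects:

* track table:   ``cell_id,parent_id,time_min,length_um`` (parent empty for
  roots; extra columns tolerated);
* cycle table:   ``cell_id,birth_time_min,birth_size_um,division_time_min,
  division_size_um,division_age_min,growth_rate_per_min,septum_ratio,
  complete``;
* division rate: ``grid_value,rate_per_min,reliable``;
* density grid:  axis header lines (``# axis <name>: v0 v1 ...``) followed
  by the dense value matrix;
* stable distributions get a JSON sidecar with the Malthus coefficient,
  residual, iteration count and a config echo.

Run configurations are YAML (schema version 1); every run echoes its
resolved configuration so any artifact can be regenerated from the echo and
the seed alone.
"""
from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
import yaml

from .kde import DensityGrid
from .pde import SolverConfig, StableDistribution
from .tracks import read_tracks, write_tracks  # re-exported

__all__ = ["read_tracks", "write_tracks", "write_cycles", "read_cycles",
           "write_density", "read_density", "write_stable",
           "load_run_config", "dump_run_config", "CONFIG_SCHEMA_VERSION"]

CONFIG_SCHEMA_VERSION = 1


def write_cycles(cycles: pd.DataFrame, path) -> None:
    out = cycles.copy()
    out["complete"] = out["complete"].astype(bool)
    out.to_csv(path, index=False)


def read_cycles(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["complete"] = df["complete"].astype(bool)
    return df


def write_density(dens: DensityGrid, path) -> None:
    with open(path, "w") as fh:
        for name, grid in zip(dens.names, dens.grids):
            fh.write(f"# axis {name}: " +
                     " ".join(f"{g:.8g}" for g in grid) + "\n")
        np.savetxt(fh, np.atleast_2d(dens.values), fmt="%.8e")


def read_density(path) -> DensityGrid:
    names, grids = [], []
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("# axis "):
            head, _, rest = line[len("# axis "):].partition(":")
            names.append(head.strip())
            grids.append(np.array([float(v) for v in rest.split()]))
        elif line.strip():
            body.append(line)
    vals = np.loadtxt(body)
    if len(names) == 1:
        vals = vals.ravel()
    return DensityGrid(tuple(names), tuple(grids), vals, normalized=True)


def write_stable(sol: StableDistribution, path, cfg: SolverConfig | None = None,
                 extra: dict | None = None) -> None:
    """Density in the DensityGrid dialect plus a JSON metadata sidecar."""
    write_density(sol.density, path)
    meta = {
        "malthus_per_min": sol.malthus,
        "residual": sol.residual,
        "iterations": sol.iterations,
        "converged": sol.converged,
    }
    if cfg is not None:
        meta["solver_config"] = dataclasses.asdict(cfg)
    if extra:
        meta.update(extra)
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_run_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    version = cfg.pop("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema version {version}")
    return cfg


def dump_run_config(cfg: dict, path) -> None:
    payload = {"schema_version": CONFIG_SCHEMA_VERSION, **cfg}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
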