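"""Division rates (hazards) tabulated on a grid.

The division rate B(.) is the instantaneous probability of division per unit
time: a cell of age a (resp. size x) divides in [t, t+dt) with probability
B_a(a)dt (resp. B_s(x)dt).  ``DivisionRate`` holds a nonparametric estimate or
an analytic hazard tabulated on a uniform grid, together with a mask marking
the range over which the values are statistically reliable and a declared
extrapolation rule used outside the grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DivisionRate"]

_INDICES = {"age", "size"}
_EXTRAP = {"constant", "zero"}


@dataclass
class DivisionRate:
    """Nonparametric hazard on a uniform grid with an interpolation contract.

    Between grid nodes the rate is linearly interpolated.  Below the first
    node the first value is used; above the last node the behaviour follows
    ``extrapolation``: ``"constant"`` continues the last value, ``"zero"``
    drops to zero (which makes lifetimes potentially divergent — the
    simulator raises in that case).
    """

    index: str                      # 'age' or 'size'
    grid: np.ndarray                # uniform, increasing (min or µm)
    values: np.ndarray              # rate in min^-1, >= 0, finite
    reliable: np.ndarray = None     # bool mask, same shape as grid
    extrapolation: str = "constant"

    def __post_init__(self):
        if self.index not in _INDICES:
            raise ValueError(f"index must be one of {_INDICES}, got {self.index!r}")
        if self.extrapolation not in _EXTRAP:
            raise ValueError(f"extrapolation must be one of {_EXTRAP}")
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("grid must be 1-D with at least two nodes")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.values.shape != self.grid.shape:
            raise ValueError("values and grid shapes differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("division rate must be finite everywhere")
        if np.any(self.values < 0):
            raise ValueError("division rate must be non-negative")
        if self.reliable is None:
            self.reliable = np.ones_like(self.grid, dtype=bool)
        else:
            self.reliable = np.asarray(self.reliable, dtype=bool)

    # ---------------------------------------------------------------- factory
    @classmethod
    def from_function(cls, fn, index: str, grid, extrapolation: str = "constant"
                      ) -> "DivisionRate":
        grid = np.asarray(grid, dtype=float)
        return cls(index=index, grid=grid, values=np.maximum(fn(grid), 0.0),
                   extrapolation=extrapolation)

    # ------------------------------------------------------------- evaluation
    def __call__(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        right = self.values[-1] if self.extrapolation == "constant" else 0.0
        out = np.interp(q, self.grid, self.values,
                        left=self.values[0], right=right)
        return out

    @property
    def tail_rate(self) -> float:
        """Rate continued beyond the last grid node."""
        return float(self.values[-1]) if self.extrapolation == "constant" else 0.0

    # ------------------------------------------------------------------- I/O
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "grid_value": self.grid,
            "rate_per_min": self.values,
            "reliable": self.reliable.astype(int),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, index: str, extrapolation: str = "constant"
                 ) -> "DivisionRate":
        df = pd.read_csv(path)
        return cls(index=index, grid=df["grid_value"].to_numpy(),
                   values=df["rate_per_min"].to_numpy(),
                   reliable=df["reliable"].to_numpy().astype(bool),
                   extrapolation=extrapolation)
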