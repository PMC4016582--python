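"""Nonparametric estimation of division rates from cycle data.

Both estimators are occurrence/exposure (survival-hazard) constructions:

* age:  B_a(a) = f(a) / S(a), with f the kernel density of ages at division
  and S(a) = 1 - F(a) the fraction of cycles still undivided at age a;
* size: B_s(x) = v(x) * psi(x) / pi(x), with psi the kernel density of sizes
  at division, pi(x) the at-risk fraction (cycles with x_b <= x < x_d) and
  v(x) the growth law — dividing by v converts the per-unit-size hazard into
  a per-unit-time rate.

These are consistent for the respective models and need no genealogical
weighting: conditional on being at risk at a given age or size, the hazard
is the same on every branch of the tree, so full-tree and mother-machine
data are handled identically.  Where the denominator falls below a floor
(``s_min`` / ``p_min``) the estimate is no longer reliable; the rate is
continued as a constant there (so downstream PDE solvers receive a finite
hazard on the whole grid) and the reliability mask records the affected
range.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .growthlaw import GrowthLaw
from .hazard import DivisionRate
from .kde import DensityGrid, kde1d, make_grid, smoothed_cdf

__all__ = ["estimate_age_rate", "estimate_size_rate"]


def _complete(cycles: pd.DataFrame, min_cycles: int) -> pd.DataFrame:
    comp = cycles[cycles["complete"]]
    if len(comp) == 0:
        raise ValueError("no complete cycles to estimate from")
    if len(comp) < min_cycles:
        warnings.warn(
            f"only {len(comp)} complete cycles (< {min_cycles}); the "
            "estimate will have a wide unreliable range", stacklevel=2)
    frac_incomplete = 1.0 - len(comp) / len(cycles)
    if frac_incomplete > 0.10:
        warnings.warn(
            f"{100 * frac_incomplete:.0f}% of cycles are incomplete and "
            "excluded; right-censoring bias possible", stacklevel=2)
    return comp


def estimate_age_rate(cycles: pd.DataFrame,
                      grid: np.ndarray | None = None,
                      s_min: float = 0.02,
                      min_cycles: int = 100,
                      bandwidth="silverman",
                      boxcar: float | None = None) -> DivisionRate:
    """Estimate the age-indexed division rate B_a(a) from complete cycles.

    Division ages live on the acquisition-frame lattice, so the kernel is a
    Gaussian convolved with a box of one frame width (``boxcar``, inferred
    from the sample when not given): the box matches the frame-rounding
    error and removes the lattice comb without extra smoothing.
    """
    comp = _complete(cycles, min_cycles)
    ages = comp["division_age_min"].to_numpy(dtype=float)
    if grid is None:
        grid = make_grid(1.05 * ages.max())
    grid = np.asarray(grid, dtype=float)
    if boxcar is None:
        pos = np.unique(ages)
        boxcar = float(np.min(np.diff(pos))) if pos.size > 1 else 0.0
    f = kde1d(ages, grid=grid, bandwidth=bandwidth, boxcar=boxcar)
    da = f.spacing()
    # numerator rescaled to unit midpoint mass so that it is consistent
    # with the closed-form smoothed CDF below
    fv = f.values / (f.values.sum() * da)
    S = np.clip(1.0 - smoothed_cdf(ages, grid, f.bandwidths[0],
                                   boxcar=f.boxcars[0]), 0.0, 1.0)
    reliable = S >= s_min
    if not np.any(reliable):
        raise ValueError("survival never exceeds s_min; cannot estimate")
    B = np.zeros_like(grid)
    B[reliable] = fv[reliable] / S[reliable]
    last = np.flatnonzero(reliable)[-1]
    B[last + 1:] = B[last]
    return DivisionRate(index="age", grid=grid, values=B, reliable=reliable,
                        extrapolation="constant")


def estimate_size_rate(cycles: pd.DataFrame,
                       growth_law: GrowthLaw,
                       grid: np.ndarray | None = None,
                       p_min: float = 0.02,
                       min_cycles: int = 100,
                       bandwidth="silverman") -> DivisionRate:
    """Estimate the size-indexed division rate B_s(x) from complete cycles.

    Below the smallest observed birth size no cell is at risk and the rate
    is set to zero; above the reliable support (at-risk fraction < p_min)
    the last reliable value is continued.
    """
    comp = _complete(cycles, min_cycles)
    x_b = comp["birth_size_um"].to_numpy(dtype=float)
    x_d = comp["division_size_um"].to_numpy(dtype=float)
    if grid is None:
        grid = make_grid(1.05 * x_d.max())
    grid = np.asarray(grid, dtype=float)
    v = growth_law.rate(grid)
    obs = (grid >= x_b.min()) & (grid <= x_d.max())
    if not np.any(v[obs] > 0):
        raise ValueError("growth law is zero on the observed size range")
    psi = kde1d(x_d, grid=grid, bandwidth=bandwidth)
    # at-risk fraction pi(x) = P(x_b <= x < x_d), exact empirical version
    xs_b = np.sort(x_b)
    xs_d = np.sort(x_d)
    n = float(len(comp))
    pi = (np.searchsorted(xs_b, grid, side="right")
          - np.searchsorted(xs_d, grid, side="right")) / n
    reliable = (pi >= p_min) & (v > 0)
    if not np.any(reliable):
        raise ValueError("at-risk fraction never exceeds p_min")
    B = np.zeros_like(grid)
    B[reliable] = v[reliable] * psi.values[reliable] / pi[reliable]
    idx = np.flatnonzero(reliable)
    B[idx[-1] + 1:] = B[idx[-1]]      # constant continuation above support
    # below the smallest birth size the rate stays zero
    return DivisionRate(index="size", grid=grid, values=B, reliable=reliable,
                        extrapolation="constant")
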