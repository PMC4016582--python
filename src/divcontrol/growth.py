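"""Single-cell growth-law characterization.

Answers three questions about a dataset: (i) is single-cell growth linear or
exponential (per-cell fits compared through R^2 on the length scale); (ii)
over which size range is growth proportional to length (binned
length-increment curve and the thresholds x_min/x_max outside which
proportionality fails); (iii) how variable are the per-cell growth rate and
the septum position (kernel-smoothed distributions and CVs).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kde import DensityGrid, kde1d, make_grid

__all__ = ["GrowthFitResult", "IncrementCurve", "NoiseSummary",
           "fit_single_cell_growth", "fit_all_cells", "increment_curve",
           "noise_summary", "fit_polynomial_cap"]


@dataclass(frozen=True)
class GrowthFitResult:
    cell_id: int
    rate: float             # exponential rate v_i (min^-1)
    initial_length: float   # fitted length at the first time point (µm)
    r2_linear: float
    r2_exponential: float


@dataclass
class IncrementCurve:
    """Binned mean length increment per acquisition step vs length."""

    bin_centers: np.ndarray   # µm
    mean_increment: np.ndarray  # µm per acquisition step
    sem: np.ndarray
    count: np.ndarray
    slope: float              # weighted linear fit over fit_range
    intercept: float
    prop_slope: float         # weighted through-origin (proportional) slope
    fit_range: tuple
    x_min: float              # lower proportionality threshold (µm)
    x_max: float              # upper proportionality threshold (µm)
    acquisition_dt: float     # min

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center_um": self.bin_centers,
            "mean_increment_um": self.mean_increment,
            "sem_um": self.sem,
            "count": self.count,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class NoiseSummary:
    rate_density: DensityGrid
    rate_cv: float
    rate_normality: tuple      # (statistic, p) of D'Agostino-Pearson test
    septum_density: DensityGrid
    septum_cv: float
    septum_normality: tuple


def _r2(y, yhat) -> float:
    ss_tot = np.sum((y - y.mean()) ** 2)
    ss_res = np.sum((y - yhat) ** 2)
    if ss_tot == 0:
        return np.nan
    return 1.0 - ss_res / ss_tot


def fit_single_cell_growth(times, lengths, cell_id: int = -1
                           ) -> GrowthFitResult:
    """Linear and exponential fits of one cell's length time series.

    The linear model is fitted by ordinary least squares; the exponential
    model by least squares on log-length (its slope is the growth rate v_i).
    Both R^2 values are computed on the original length scale so the two
    models are directly comparable.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if t.size < 3 or np.unique(t).size < 3:
        raise ValueError("growth fit needs at least 3 distinct time points")
    if np.any(y <= 0):
        raise ValueError("growth fit needs positive lengths")
    b1, b0 = np.polyfit(t, y, 1)
    lin_hat = b0 + b1 * t
    c1, c0 = np.polyfit(t, np.log(y), 1)
    exp_hat = np.exp(c0 + c1 * t)
    return GrowthFitResult(
        cell_id=cell_id,
        rate=float(c1),
        initial_length=float(np.exp(c0 + c1 * t[0])),
        r2_linear=float(_r2(y, lin_hat)),
        r2_exponential=float(_r2(y, exp_hat)),
    )


def fit_all_cells(tracks: pd.DataFrame, min_points: int = 3) -> pd.DataFrame:
    """Per-cell growth fits for every cell with enough frames."""
    rows = []
    for cid, grp in tracks.groupby("cell_id", sort=True):
        if len(grp) < min_points:
            continue
        res = fit_single_cell_growth(grp["time_min"], grp["length_um"],
                                     cell_id=int(cid))
        rows.append(res)
    if not rows:
        raise ValueError("no cell has enough frames for a growth fit")
    return pd.DataFrame([r.__dict__ for r in rows])


def increment_curve(tracks: pd.DataFrame,
                    bin_width: float = 0.2,
                    fit_range: tuple | None = None,
                    min_count: int = 50,
                    dev_mult: float = 2.0,
                    rel_tol: float = 0.02) -> IncrementCurve:
    """Binned mean length increment per time step as a function of length.

    For every pair of consecutive frames of the same cell (increments never
    cross a division) the pair (length, delta-length) is recorded and binned
    by length.  Bins with fewer than ``min_count`` pairs carry no estimate.
    A weighted linear fit over ``fit_range`` (defaulting to the interquartile
    length range) gives the proportionality line; the thresholds x_min/x_max
    are the outermost bin centers, searched outward from the fit range, at
    which the binned mean still agrees with the through-origin fit to within
    ``dev_mult`` standard errors plus a ``rel_tol`` relative floor (the
    floor keeps the rule meaningful when bins are so well populated that
    the standard error falls below any practically relevant deviation).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    df = tracks.sort_values(["cell_id", "time_min"], kind="mergesort")
    same = df["cell_id"].to_numpy()[1:] == df["cell_id"].to_numpy()[:-1]
    lengths = df["length_um"].to_numpy()
    times = df["time_min"].to_numpy()
    x = lengths[:-1][same]
    dx = (lengths[1:] - lengths[:-1])[same]
    dts = (times[1:] - times[:-1])[same]
    step = float(np.median(dts)) if dts.size else np.nan
    if x.size == 0:
        raise ValueError("no consecutive observation pairs")

    nbins = int(np.ceil(x.max() / bin_width))
    idx = np.minimum((x / bin_width).astype(int), nbins - 1)
    count = np.bincount(idx, minlength=nbins).astype(float)
    mean = np.full(nbins, np.nan)
    sem = np.full(nbins, np.nan)
    sums = np.bincount(idx, weights=dx, minlength=nbins)
    sq = np.bincount(idx, weights=dx * dx, minlength=nbins)
    ok = count >= max(min_count, 2)
    mean[ok] = sums[ok] / count[ok]
    var = np.maximum(sq[ok] / count[ok] - mean[ok] ** 2, 0.0)
    sem[ok] = np.sqrt(var / count[ok])
    centers = (np.arange(nbins) + 0.5) * bin_width

    if fit_range is None:
        fit_range = tuple(np.percentile(x, [25, 75]))
    in_fit = ok & (centers >= fit_range[0]) & (centers <= fit_range[1])
    if not np.any(in_fit):
        raise ValueError("no populated bins inside the fit range")
    w = 1.0 / np.maximum(sem[in_fit], 1e-12) ** 2
    xc, yc = centers[in_fit], mean[in_fit]
    if in_fit.sum() >= 2:
        A = np.vstack([xc, np.ones_like(xc)]).T
        W = np.sqrt(w)
        slope, intercept = np.linalg.lstsq(A * W[:, None], yc * W, rcond=None)[0]
    else:
        slope, intercept = yc[0] / xc[0], 0.0
    prop_slope = float(np.sum(w * xc * yc) / np.sum(w * xc * xc))

    # proportionality thresholds, searched outward from the fit range
    dev = np.abs(mean - prop_slope * centers)
    tol = dev_mult * np.maximum(sem, 1e-12) + rel_tol * prop_slope * centers
    good = ok & (dev <= tol)
    fit_bins = np.flatnonzero(in_fit)
    lo = fit_bins[0]
    while lo - 1 >= 0 and ok[lo - 1] and good[lo - 1]:
        lo -= 1
    hi = fit_bins[-1]
    while hi + 1 < nbins and ok[hi + 1] and good[hi + 1]:
        hi += 1
    return IncrementCurve(
        bin_centers=centers, mean_increment=mean, sem=sem, count=count,
        slope=float(slope), intercept=float(intercept),
        prop_slope=prop_slope, fit_range=tuple(fit_range),
        x_min=float(centers[lo]), x_max=float(centers[hi]),
        acquisition_dt=step,
    )


def fit_polynomial_cap(curve: IncrementCurve, degree: int = 3) -> np.ndarray:
    """Cubic (by default) interpolation of the increment-rate curve.

    Returns polynomial coefficients (highest first) of p(x) such that
    v(x) = max(p(x), 0) approximates the measured growth rate dx/dt over the
    populated bins; used as the out-of-range growth cap of the timer model.
    """
    ok = np.isfinite(curve.mean_increment)
    if ok.sum() < degree + 1:
        raise ValueError("too few populated bins for the polynomial cap fit")
    xc = curve.bin_centers[ok]
    yc = curve.mean_increment[ok] / curve.acquisition_dt
    wc = np.sqrt(curve.count[ok])
    return np.polyfit(xc, yc, degree, w=wc)


def noise_summary(cycles: pd.DataFrame, min_cycles: int = 30) -> NoiseSummary:
    """Empirical growth-rate and septum-ratio distributions and CVs."""
    comp = cycles[cycles["complete"]]
    rates = comp["growth_rate_per_min"].dropna().to_numpy()
    septa = comp["septum_ratio"].dropna().to_numpy()
    if min(rates.size, septa.size) < min_cycles:
        raise ValueError(f"noise summary needs at least {min_cycles} "
                         "complete cycles")
    rate_cv = float(np.std(rates, ddof=1) / np.mean(rates))
    septum_cv = float(np.std(septa, ddof=1) / np.mean(septa))
    rate_grid = make_grid(2.0 * rates.max(), 256)
    rate_dens = kde1d(rates, grid=rate_grid)
    if np.ptp(septa) > 0:
        sept_dens = kde1d(septa, grid=make_grid(1.0, 256), reflect=False)
    else:  # perfectly symmetric division: degenerate spike at the mean
        grid = make_grid(1.0, 256)
        vals = np.zeros_like(grid)
        vals[np.argmin(np.abs(grid - septa.mean()))] = 1.0
        sept_dens = DensityGrid(("value",), (grid,), vals).normalize()
    return NoiseSummary(
        rate_density=rate_dens,
        rate_cv=rate_cv,
        rate_normality=tuple(map(float, stats.normaltest(rates))),
        septum_density=sept_dens,
        septum_cv=septum_cv,
        septum_normality=(tuple(map(float, stats.normaltest(septa)))
                          if np.ptp(septa) > 0 else (np.nan, np.nan)),
    )
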