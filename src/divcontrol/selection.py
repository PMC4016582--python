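"""Timer-vs-sizer model discrimination and robustness analysis.

The headline analysis: from a single-cell track table, estimate both an
age-indexed and a size-indexed division rate, reconstruct the stable
age-size distribution under each model, and compare each reconstruction to
the empirical age-size distribution with a normalized L2 distance

    D = sqrt( integral (f - g)^2 / integral f^2 ),

where f is the empirical (reference) density.  D is reported as a
percentage; D = 0 iff the distributions coincide on the grid and D = 100%
against the zero density.  A small D means a good fit; the preferred model
is the one with the smaller distance.  Two diagnostics complement the
distances: the correlation between division age and birth size (absent
under timer control, strongly negative under sizer control) and
distance-vs-noise robustness scans of the sizer model.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .cycles import extract_cycles, occupation_measure
from .estimate import estimate_age_rate, estimate_size_rate
from .growth import increment_curve, fit_polynomial_cap
from .growthlaw import GrowthLaw
from .hazard import DivisionRate
from .kde import DensityGrid, kde2d, make_grid, smooth_density
from .pde import (NoStableDistributionError, SolverConfig, StableDistribution,
                  rate_density_truncnorm, septum_kernel_truncnorm,
                  solve_size_profile, solve_stable,
                  solve_with_growth_variability, solve_with_septum_noise)
from .simulate import SimConfig, apply_measurement_layer

__all__ = ["FitDistance", "FitReport", "EvalConfig", "distance",
           "correlation_diagnostic", "evaluate_models", "robustness_scan"]


@dataclass(frozen=True)
class FitDistance:
    d: float              # fraction; D = 0 identical, 1 against zero density
    numerator: float      # integral (f-g)^2
    denominator: float    # integral f^2
    grid_names: tuple

    @property
    def percent(self) -> float:
        return 100.0 * self.d


def distance(f: DensityGrid, g: DensityGrid) -> FitDistance:
    """Normalized L2 distance between two densities on a common grid.

    f is the reference (experimental) density; the normalization is by the
    reference's squared L2 norm, with a square root so D reads as a relative
    amplitude.
    """
    if not f.same_grid_as(g):
        raise ValueError("distance requires identical grids")

    def integ(vals):
        out = vals
        for ax in range(f.ndim - 1, -1, -1):
            out = np.trapezoid(out, f.grids[ax], axis=ax)
        return float(out)

    num = integ((f.values - g.values) ** 2)
    den = integ(f.values ** 2)
    if den <= 0:
        raise ValueError("reference density has zero norm")
    return FitDistance(d=float(np.sqrt(num / den)), numerator=num,
                       denominator=den, grid_names=f.names)


def correlation_diagnostic(cycles: pd.DataFrame, n_perm: int = 10_000,
                           seed: int = 0, min_cycles: int = 30):
    """Pearson correlation between division age and birth size.

    Under timer control the division age is independent of birth size; under
    sizer control with exponential growth, cells born large need less time
    to reach dividing sizes, so the correlation is strongly negative.  The
    p-value comes from a seeded permutation test (no distributional
    assumptions).
    """
    comp = cycles[cycles["complete"]]
    if len(comp) < min_cycles:
        raise ValueError(f"correlation diagnostic needs >= {min_cycles} "
                         "complete cycles")
    x = comp["birth_size_um"].to_numpy(dtype=float)
    y = comp["division_age_min"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant column: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    r = float((xc * yc).sum() / denom)
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(n_perm, 10_000_000 // max(1, x.size)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((m, x.size)), axis=1)
        r_perm = (xc[idx] * yc[None, :]).sum(axis=1) / denom
        hits += int(np.sum(np.abs(r_perm) >= abs(r) - 1e-15))
        done += m
    p = (1 + hits) / (1 + n_perm)
    return r, float(p)


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------

@dataclass
class EvalConfig:
    topology: str = "full_tree"
    discard_before: float = 0.0
    generation_window: tuple | None = None
    n_age: int = 128
    n_size: int = 128
    s_min: float = 0.02
    p_min: float = 0.02
    min_cycles: int = 100
    d_threshold: float = 0.25        # sizer acceptance threshold on D
    n_perm: int = 2000
    tol: float = 1e-8
    max_iter: int = 60_000
    seed: int = 0


@dataclass
class FitReport:
    d_age: FitDistance
    d_size: FitDistance
    correlation_r: float
    correlation_p: float
    preferred: str
    timer_converged: bool
    sizer_converged: bool
    v_hat: float
    x_min: float
    x_max: float
    cap_coeffs: tuple
    n_cycles: int
    rate_age: DivisionRate
    rate_size: DivisionRate
    empirical: DensityGrid
    timer_solution: StableDistribution
    sizer_solution: StableDistribution
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "d_age_pct": self.d_age.percent,
            "d_size_pct": self.d_size.percent,
            "correlation_r": self.correlation_r,
            "correlation_p": self.correlation_p,
            "preferred": self.preferred,
            "timer_converged": self.timer_converged,
            "sizer_converged": self.sizer_converged,
            "v_hat_per_min": self.v_hat,
            "x_min_um": self.x_min,
            "x_max_um": self.x_max,
            "cap_coeffs": list(self.cap_coeffs),
            "n_cycles": self.n_cycles,
            "malthus_timer_per_min": self.timer_solution.malthus,
            "malthus_sizer_per_min": self.sizer_solution.malthus,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _config_hash(cfg: EvalConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def evaluate_models(tracks: pd.DataFrame, cfg: EvalConfig | None = None
                    ) -> FitReport:
    """Fit the timer and sizer models to a track table and compare them.

    Pipeline: cycle extraction -> single-cell growth analysis (mean rate,
    proportionality thresholds, polynomial growth cap for the timer model)
    -> nonparametric estimation of B_a and B_s -> stable age-size
    distribution under each restriction (timer: capped growth; sizer: pure
    exponential) -> normalized L2 distances to the empirical age-size
    distribution -> correlation diagnostic.  A model whose iteration does
    not stabilize (the theoretical fate of timer control under exponential
    growth) is scored on its last iterate and flagged unconverged.
    """
    cfg = cfg or EvalConfig()

    def stage(name, fn, *a, **k):
        try:
            return fn(*a, **k)
        except NoStableDistributionError:
            raise
        except Exception as exc:
            raise RuntimeError(f"[{name}] {exc}") from exc

    cycles = stage("extract_cycles", extract_cycles, tracks,
                   discard_before=cfg.discard_before,
                   generation_window=cfg.generation_window)
    comp = cycles[cycles["complete"]]
    if len(comp) < cfg.min_cycles:
        raise ValueError(
            f"insufficient cycles: {len(comp)} complete < {cfg.min_cycles}")
    v_hat = float(comp["growth_rate_per_min"].dropna().mean())
    dt_acq = float(tracks.sort_values(["cell_id", "time_min"])
                   .groupby("cell_id")["time_min"].diff().dropna().median())

    occ = stage("occupation_measure", occupation_measure, tracks, cycles,
                discard_before=cfg.discard_before)
    a_hi = 1.1 * float(occ["age_min"].max())
    x_hi = 1.2 * float(max(occ["size_um"].max(),
                           comp["division_size_um"].max()))
    grid_a = make_grid(a_hi, cfg.n_age)
    grid_x = make_grid(x_hi, cfg.n_size)

    # lattice ages stand for the interval up to the next frame: shift by half
    # a frame and convolve with a one-frame boxcar along the age axis
    emp = stage("kde2d", kde2d, occ["age_min"] + 0.5 * dt_acq, occ["size_um"],
                grid_a=grid_a, grid_x=grid_x, boxcars=(dt_acq, 0.0))

    B_a = stage("estimate_age_rate", estimate_age_rate, cycles, grid=grid_a,
                s_min=cfg.s_min, min_cycles=cfg.min_cycles)
    law_exp = GrowthLaw.exponential(v_hat)
    B_s = stage("estimate_size_rate", estimate_size_rate, cycles, law_exp,
                grid=grid_x, p_min=cfg.p_min, min_cycles=cfg.min_cycles)

    # timer growth law: exponential core, cubic increment-curve cap outside.
    # The core rate comes from the increment curve itself (geometric mean
    # step ratio), not from the mean per-cell OLS rate: cells that spend
    # part of their cycle outside the proportional range bias the per-cell
    # rates low under capped growth.
    try:
        curve = increment_curve(tracks)
        coeffs = fit_polynomial_cap(curve)
        v_core = np.log1p(curve.prop_slope) / curve.acquisition_dt
        law_timer = GrowthLaw.from_polynomial(v_core, curve.x_min,
                                              curve.x_max, coeffs)
        x_min, x_max = curve.x_min, curve.x_max
    except ValueError:
        warnings.warn("increment curve unusable; timer model falls back to "
                      "a constant-capped growth law", stacklevel=2)
        q = np.percentile(comp["birth_size_um"], [5, 95])
        law_timer = GrowthLaw.capped_constant(v_hat, q[0], q[1])
        x_min, x_max = float(q[0]), float(q[1])
        coeffs = ()

    scfg = SolverConfig(a_max=a_hi, x_max=x_hi, n_age=cfg.n_age,
                        n_size=cfg.n_size, tol=cfg.tol, max_iter=cfg.max_iter,
                        topology=cfg.topology)

    def solve(model, B, law):
        try:
            return solve_stable(model, B, law, scfg), True
        except NoStableDistributionError as exc:
            return exc.state, False

    timer_sol, timer_ok = solve("age", B_a, law_timer)
    sizer_sol, sizer_ok = solve("size", B_s, law_exp)

    # compare on equal terms: the KDE targets the kernel-smoothed density,
    # so the model predictions are smoothed with the estimator's own kernel
    smooth_timer = smooth_density(timer_sol.density, emp.bandwidths,
                                  emp.boxcars)
    smooth_sizer = smooth_density(sizer_sol.density, emp.bandwidths,
                                  emp.boxcars)
    d_age = stage("distance", distance, emp, smooth_timer)
    d_size = stage("distance", distance, emp, smooth_sizer)
    r, p = stage("correlation", correlation_diagnostic, cycles,
                 n_perm=cfg.n_perm, seed=cfg.seed)

    return FitReport(
        d_age=d_age, d_size=d_size,
        correlation_r=r, correlation_p=p,
        preferred="sizer" if d_size.d < d_age.d else "timer",
        timer_converged=timer_ok, sizer_converged=sizer_ok,
        v_hat=v_hat, x_min=x_min, x_max=x_max,
        cap_coeffs=tuple(np.round(np.atleast_1d(coeffs), 6)),
        n_cycles=int(len(comp)),
        rate_age=B_a, rate_size=B_s, empirical=emp,
        timer_solution=timer_sol, sizer_solution=sizer_sol,
        provenance={"seed": cfg.seed, "config_hash": _config_hash(cfg),
                    "acquisition_dt_min": dt_acq},
    )


# --------------------------------------------------------------------------
# robustness scans
# --------------------------------------------------------------------------

def robustness_scan(B_s: DivisionRate, growth: GrowthLaw, noise_type: str,
                    cv_list, cfg: SolverConfig | None = None,
                    sim_config: SimConfig | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Distance of the sizer stable size distribution from its zero-noise
    counterpart as a function of the noise level.

    ``noise_type``: 'growth_rate' and 'septum' solve the corresponding
    noise-extended PDE per CV; 'division_time_measurement' runs a stochastic
    simulation, perturbs the observed division times, re-estimates the
    division rate and re-solves, comparing against the noiseless pipeline.
    Returns a DataFrame with columns ``cv`` and ``distance_pct``.
    """
    cvs = list(cv_list)
    if any(c < 0 for c in cvs) or sorted(cvs) != cvs:
        raise ValueError("cv_list must be nonnegative and sorted")
    cfg = cfg or SolverConfig()
    rows = []

    if noise_type in ("growth_rate", "septum"):
        base = solve_size_profile(B_s, growth, cfg).size_marginal
        for cv in cvs:
            try:
                if cv == 0:
                    pert = base
                elif noise_type == "growth_rate":
                    rho = rate_density_truncnorm(growth.v, cv, cfg.n_rate)
                    pert = solve_with_growth_variability(
                        B_s, rho, growth, cfg).size_marginal
                else:
                    q = septum_kernel_truncnorm(cv)
                    pert = solve_with_septum_noise(
                        B_s, q, growth, cfg).size_marginal
            except NoStableDistributionError as exc:
                raise NoStableDistributionError(
                    f"scan failed at CV={cv}: {exc}", state=exc.state)
            rows.append((cv, distance(base, pert).percent))
        return pd.DataFrame(rows, columns=["cv", "distance_pct"])

    if noise_type != "division_time_measurement":
        raise ValueError(f"unknown noise type {noise_type!r}")
    if sim_config is None:
        raise ValueError("division_time_measurement scan needs a sim_config")

    from .simulate import simulate_mother_machine, simulate_population

    simulate = (simulate_population if sim_config.topology == "full_tree"
                else simulate_mother_machine)
    tracks0 = simulate(sim_config)
    gen_window = (None if sim_config.topology == "full_tree"
                  else (5, int(sim_config.generations)))

    def pipeline(tracks):
        cycles = extract_cycles(tracks, generation_window=gen_window)
        comp = cycles[cycles["complete"]]
        v_hat = float(comp["growth_rate_per_min"].dropna().mean())
        grid = make_grid(cfg.x_max, cfg.n_size)
        B = estimate_size_rate(cycles, GrowthLaw.exponential(v_hat), grid=grid)
        return solve_size_profile(B, GrowthLaw.exponential(v_hat),
                                  cfg).size_marginal

    base = pipeline(tracks0)
    for cv in cvs:
        if cv == 0:
            rows.append((cv, 0.0))
            continue
        noisy_cfg = SimConfig(**{**sim_config.__dict__,
                                 "division_time_noise_cv": cv})
        noisy = apply_measurement_layer(tracks0, noisy_cfg)
        rows.append((cv, distance(base, pipeline(noisy)).percent))
    return pd.DataFrame(rows, columns=["cv", "distance_pct"])
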