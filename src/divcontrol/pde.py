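"""Structured-population PDE solvers for timer and sizer division control.

The central object is the age-and-size-structured growth-fragmentation
equation for the density n(t,a,x) of cells of age a and size x,

    dn/dt + dn/da + d(v(x) n)/dx = -B(a,x) n,
    n(t, a=0, x) = 4 * integral B(a, 2x) n(t, a, 2x) da     (full tree),

whose timer (B = B_a(a)) and sizer (B = B_s(x)) restrictions are the two
competing models of division control.  After transients the population
enters the stable regime n(t,a,x) ~ exp(lambda*t) N(a,x); the solvers return
the normalized stable distribution N and the Malthus coefficient lambda.

Discretization: first-order upwind finite volumes on uniform cell-centered
grids (2^7 nodes per axis by default), explicit Euler time stepping with a
CFL-limited step, renormalization to unit mass at every step (which removes
the exp(lambda*t) factor; lambda is recovered from the per-step growth
factor), iterated until the sup-norm change per step falls below the
tolerance.  The fragmentation gain at 2x is evaluated by linear
interpolation, zero beyond the size domain.  For sparse-tree (mother
machine) data only one daughter is followed per division, so the renewal
factor 4 becomes 2 (the size Jacobian survives, the number doubling does
not) and lambda is approximately zero.

Two extended sizer models quantify robustness to phenotypic noise: one adds
i.i.d. variability of the single-cell growth rate (an (x, v')-structured
equation), the other a septum-positioning kernel q(theta) that splits a
dividing mother of size y into daughters of size theta*y and (1-theta)*y.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .growthlaw import GrowthLaw
from .hazard import DivisionRate
from .kde import DensityGrid, make_grid

__all__ = ["SolverConfig", "StableDistribution", "NoStableDistributionError",
           "solve_stable", "solve_size_profile",
           "solve_with_growth_variability", "solve_with_septum_noise",
           "rate_density_truncnorm", "septum_kernel_truncnorm"]


class NoStableDistributionError(RuntimeError):
    """Raised when the iteration fails to reach a stable distribution.

    For timer control with uncapped exponential growth this is the expected
    theoretical outcome, not a numerical accident.  The last iterate is
    attached as ``state`` (``converged=False``).
    """

    def __init__(self, msg, state=None):
        super().__init__(msg)
        self.state = state


@dataclass
class SolverConfig:
    a_max: float = 60.0          # min
    x_max: float = 10.0          # µm
    n_age: int = 128
    n_size: int = 128
    cfl_safety: float = 0.9
    tol: float = 1e-8
    max_iter: int = 60_000
    topology: str = "full_tree"  # 'full_tree' | 'sparse_tree'
    n_rate: int = 100            # growth-rate grid points (extended model)
    lambda_window: int = 100     # steps averaged for the Malthus coefficient
    leak_tol: float = 1e-3       # tolerated fraction of divisions lost at x_max

    @property
    def renewal_factor(self) -> float:
        return 4.0 if self.topology == "full_tree" else 2.0


@dataclass
class StableDistribution:
    density: DensityGrid         # joint (age,size) or 1-D size profile
    malthus: float               # min^-1
    residual: float
    iterations: int
    converged: bool
    boundary_leak: float = 0.0   # fraction of divisions above the size domain

    @property
    def age_marginal(self) -> DensityGrid:
        return self.density.marginal("age").normalize()

    @property
    def size_marginal(self) -> DensityGrid:
        if self.density.ndim == 1:
            return self.density
        return self.density.marginal("size").normalize()


# --------------------------------------------------------------------------
# shared machinery
# --------------------------------------------------------------------------

def _interp2x(grid: np.ndarray):
    """Linear-interpolation stencil for evaluating a density at 2x.

    Returns (ilo, ihi, w, valid): f(2x_j) = (1-w)*f[ilo] + w*f[ihi], zero
    where 2x_j lies beyond the grid.
    """
    dx = grid[1] - grid[0]
    y = 2.0 * grid
    pos = (y - grid[0]) / dx
    ilo = np.floor(pos).astype(int)
    w = pos - ilo
    valid = y <= grid[-1] + 1e-12
    ilo = np.clip(ilo, 0, grid.size - 2)
    return ilo, ilo + 1, w, valid


def _at2x(f: np.ndarray, stencil, axis=-1) -> np.ndarray:
    ilo, ihi, w, valid = stencil
    if f.ndim == 1:
        out = (1 - w) * f[ilo] + w * f[ihi]
        return np.where(valid, out, 0.0)
    out = (1 - w)[None, :] * f[:, ilo] + w[None, :] * f[:, ihi]
    return np.where(valid[None, :], out, 0.0)


def _iterate(step, n0, quad, cfg: SolverConfig, dt: float):
    """Renormalized forward iteration until the sup-norm change is < tol."""
    n = n0 / quad(n0)
    log_gf = []
    res = np.inf
    it = 0
    for it in range(1, cfg.max_iter + 1):
        n_new = step(n)
        mass = quad(n_new)
        if not np.isfinite(mass) or mass <= 0:
            raise NoStableDistributionError(
                f"iteration diverged at step {it} (mass={mass})")
        n_new = n_new / mass
        log_gf.append(np.log(mass))
        if len(log_gf) > cfg.lambda_window:
            log_gf.pop(0)
        res = float(np.max(np.abs(n_new - n)))
        n = n_new
        if res < cfg.tol:
            return n, float(np.mean(log_gf) / dt), res, it, True
    return n, float(np.mean(log_gf) / dt), res, it, False


def _default_joint_init(a, x):
    n0 = (np.exp(-3.0 * a / a[-1])[:, None]
          * np.exp(-0.5 * ((x - 0.4 * x[-1]) / (0.15 * x[-1])) ** 2)[None, :])
    return n0


def _cfl_dt(cfg: SolverConfig, v_max: float, with_age: bool) -> float:
    # transport-only CFL; the division loss term is treated implicitly so
    # arbitrarily steep hazards do not restrict the step
    dx = cfg.x_max / cfg.n_size
    denom = v_max / dx
    if with_age:
        denom += cfg.n_age / cfg.a_max
    return cfg.cfl_safety / denom


# --------------------------------------------------------------------------
# age & size solver (timer and sizer restrictions)
# --------------------------------------------------------------------------

def solve_stable(model: str, B: DivisionRate, growth: GrowthLaw,
                 cfg: SolverConfig, initial: np.ndarray | None = None
                 ) -> StableDistribution:
    """Stable age-size distribution N(a,x) and Malthus coefficient.

    ``model`` selects the restriction: 'age' (timer, B must be age-indexed),
    'size' (sizer, B size-indexed) or 'age_size' (accepts either index).
    Both restrictions are simulated on the same two-dimensional
    discretization so the joint distribution and both marginals are always
    available for comparison with data.
    """
    if model not in ("age", "size", "age_size"):
        raise ValueError("model must be 'age', 'size' or 'age_size'")
    if model == "age" and B.index != "age":
        raise ValueError("timer model requires an age-indexed division rate")
    if model == "size" and B.index != "size":
        raise ValueError("sizer model requires a size-indexed division rate")

    a = make_grid(cfg.a_max, cfg.n_age)
    x = make_grid(cfg.x_max, cfg.n_size)
    da = a[1] - a[0]
    dx = x[1] - x[0]
    edges = np.arange(cfg.n_size + 1) * dx
    v_edges = growth.rate(edges)
    if B.index == "age":
        B_mat = np.broadcast_to(B(a)[:, None], (cfg.n_age, cfg.n_size))
        B_at_2x = None
    else:
        B_mat = np.broadcast_to(B(x)[None, :], (cfg.n_age, cfg.n_size))
        B_at_2x = B(2.0 * x)
    stencil = _interp2x(x)
    fac = cfg.renewal_factor
    # age advection at unit Courant number (exact shift by one age cell per
    # macro step of length da); size transport and division loss run in m
    # CFL-limited substeps within each macro step.  Exact age transport
    # avoids the upwind diffusion that would otherwise broaden the age
    # profile by several percent.
    m_sub = max(1, int(np.ceil(float(v_edges.max()) / dx * da
                               / cfg.cfl_safety)))
    dt_x = da / m_sub
    cx = dt_x / dx
    decay = 1.0 / (1.0 + dt_x * B_mat)   # implicit division loss

    def quad(n):
        return float(np.trapezoid(np.trapezoid(n, x, axis=1), a, axis=0))

    B_col = B(a)[:, None] if B.index == "age" else None

    def renewal(n):
        n2x = _at2x(n, stencil)
        if B.index == "age":
            integrand = B_col * n2x
        else:
            integrand = B_at_2x[None, :] * n2x
        return fac * integrand.sum(axis=0) * da

    def step(n):
        # exact age shift, then m substeps in which newborns accumulate
        # continuously in the emptied age-0 cell; the reported state has
        # cell i holding exactly the ages (i*da, (i+1)*da], i.e. correct
        # cell-centered semantics including the birth cell
        out = np.empty_like(n)
        out[0, :] = 0.0
        out[1:, :] = n[:-1, :]
        n = out
        for _ in range(m_sub):
            born = renewal(n)
            flux = v_edges[1:][None, :] * n      # upwind, v >= 0
            div_x = np.empty_like(n)
            div_x[:, 0] = flux[:, 0]
            div_x[:, 1:] = flux[:, 1:] - flux[:, :-1]
            n = (n - cx * div_x) * decay
            n[0, :] = n[0, :] + dt_x * born / da
        return n
    dt = da   # one macro step advances time by da

    n0 = initial if initial is not None else _default_joint_init(a, x)
    n0 = np.asarray(n0, dtype=float)
    if n0.shape != (cfg.n_age, cfg.n_size):
        raise ValueError("initial condition shape mismatch")
    if np.any(n0 < 0) or quad(n0) <= 0:
        raise ValueError("initial condition must be nonnegative with mass")

    n, lam, res, it, ok = _iterate(step, n0, quad, cfg, dt)
    # divisions whose daughters (at half the mother's size) fall beyond the
    # grid are invisible to the renewal term; a solution that is stationary
    # only because mass escapes at x_max is not a stable distribution of the
    # equation (the theoretical fate of timer control under uncapped
    # exponential growth)
    if B.index == "age":
        integrand = B(a)[:, None] * n
    else:
        integrand = B(x)[None, :] * n
    divisions = float(integrand.sum() * da * dx)
    n2x = _at2x(n, stencil)
    caught = float(((B(a)[:, None] * n2x) if B.index == "age"
                    else (B_at_2x[None, :] * n2x)).sum() * da * dx) * 2.0
    outflux = float(v_edges[-1] * n[:, -1].sum() * da)   # escape at x_max
    leak = (max(0.0, 1.0 - caught / divisions) + outflux / divisions
            if divisions > 0 else 0.0)
    dens = DensityGrid(("age", "size"), (a, x), n, normalized=True)
    state = StableDistribution(dens, lam, res, it, ok, boundary_leak=leak)
    if ok and leak > cfg.leak_tol:
        raise NoStableDistributionError(
            f"no stable distribution reached: {100 * leak:.1f}% of divisions "
            f"fall beyond the size domain (x_max={cfg.x_max}); the iterate "
            "is stationary only by domain truncation", state=state)
    if not ok:
        raise NoStableDistributionError(
            f"no stable distribution reached after {it} iterations "
            f"(residual {res:.2e} > tol {cfg.tol:.0e})", state=state)
    return state


# --------------------------------------------------------------------------
# 1-D size profile solver (shared base for the noise-extended models)
# --------------------------------------------------------------------------

def _size_transport(cfg: SolverConfig, growth: GrowthLaw, scale=1.0):
    x = make_grid(cfg.x_max, cfg.n_size)
    dx = x[1] - x[0]
    edges = np.arange(cfg.n_size + 1) * dx
    v_edges = growth.rate(edges, scale)
    return x, dx, v_edges


def solve_size_profile(B: DivisionRate, growth: GrowthLaw, cfg: SolverConfig,
                       initial: np.ndarray | None = None
                       ) -> StableDistribution:
    """Plain size-structured (sizer) model on a 1-D size grid.

    Solves dn/dt + d(v n)/dx = -B n + 4 B(2x) n(2x) (factor 2 for sparse
    trees); the reference solution against which the noise-extended models
    are compared.
    """
    if B.index != "size":
        raise ValueError("size profile requires a size-indexed rate")
    x, dx, v_edges = _size_transport(cfg, growth)
    Bx = B(x)
    B2x = B(2.0 * x)
    stencil = _interp2x(x)
    fac = cfg.renewal_factor
    dt = _cfl_dt(cfg, float(v_edges.max()), with_age=False)
    cx = dt / dx
    decay = 1.0 / (1.0 + dt * Bx)

    def quad(n):
        return float(np.trapezoid(n, x))

    def step(n):
        n2x = _at2x(n, stencil)
        flux = v_edges[1:] * n
        div_x = np.empty_like(n)
        div_x[0] = flux[0]
        div_x[1:] = flux[1:] - flux[:-1]
        return (n - cx * div_x + dt * fac * B2x * n2x) * decay

    n0 = (initial if initial is not None
          else np.exp(-0.5 * ((x - 0.4 * x[-1]) / (0.15 * x[-1])) ** 2))
    n, lam, res, it, ok = _iterate(step, np.asarray(n0, float), quad, cfg, dt)
    dens = DensityGrid(("size",), (x,), n, normalized=True)
    state = StableDistribution(dens, lam, res, it, ok)
    if not ok:
        raise NoStableDistributionError(
            f"no stable distribution reached after {it} iterations", state=state)
    return state


# --------------------------------------------------------------------------
# sizer with growth-rate variability: (x, v')-structured equation
# --------------------------------------------------------------------------

def rate_density_truncnorm(mean: float, cv: float, n_points: int = 100,
                           n_sigma: float = 3.0):
    """Truncated-Gaussian growth-rate density on the standard rate grid.

    The grid spans [0.9*v_min, 1.1*v_max] with v_min/v_max the truncation
    bounds, mirroring how the extremes of the measured single-cell rates set
    the grid in practice.
    """
    sd = cv * mean
    lo = max(0.05 * mean, mean - n_sigma * sd)
    hi = mean + n_sigma * sd
    grid = np.linspace(0.9 * lo, 1.1 * hi, n_points)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    pdf = truncnorm.pdf(grid, a, b, loc=mean, scale=sd)
    return grid, pdf


def solve_with_growth_variability(B: DivisionRate, rate_density,
                                  growth: GrowthLaw, cfg: SolverConfig
                                  ) -> StableDistribution:
    """Sizer model with i.i.d. inheritance of the single-cell growth rate.

    ``rate_density`` is ``("point", v)`` for the degenerate case or a pair
    ``(v_grid, rho)`` of a growth-rate grid and (unnormalized) density.
    Newborns draw their rate from rho independently of the mother; each rate
    slice transports with its own scaled growth law.  Returns the size
    marginal and the Malthus coefficient.
    """
    if B.index != "size":
        raise ValueError("growth-variability model requires a size rate")
    if (isinstance(rate_density, tuple) and isinstance(rate_density[0], str)
            and rate_density[0] == "point"):
        v_grid = np.array([float(rate_density[1])])
        p = np.array([1.0])
    else:
        v_grid, rho = (np.asarray(rate_density[0], float),
                       np.asarray(rate_density[1], float))
        if np.any(rho < 0):
            raise ValueError("rate density must be nonnegative")
        if rho.sum() <= 0:
            raise ValueError("rate density has no mass")
        p = rho / rho.sum()
    scales = (v_grid / growth.v)[:, None]
    x, dx, _ = _size_transport(cfg, growth)
    edges = np.arange(cfg.n_size + 1) * dx
    v_edges = growth.rate(edges[None, :], scales)     # (n_v, n_size+1)
    Bx = B(x)
    B2x = B(2.0 * x)
    stencil = _interp2x(x)
    fac = cfg.renewal_factor
    dt = _cfl_dt(cfg, float(v_edges.max()), with_age=False)
    cx = dt / dx
    decay = 1.0 / (1.0 + dt * Bx)[None, :]

    def quad(n):
        return float(np.trapezoid(n.sum(axis=0), x))

    def step(n):
        M2x = _at2x(n.sum(axis=0), stencil)
        gain = p[:, None] * (fac * B2x * M2x)[None, :]
        flux = v_edges[:, 1:] * n
        div_x = np.empty_like(n)
        div_x[:, 0] = flux[:, 0]
        div_x[:, 1:] = flux[:, 1:] - flux[:, :-1]
        return (n - cx * div_x + dt * gain) * decay

    n0 = (p[:, None]
          * np.exp(-0.5 * ((x - 0.4 * x[-1]) / (0.15 * x[-1])) ** 2)[None, :])
    n, lam, res, it, ok = _iterate(step, n0, quad, cfg, dt)
    dens = DensityGrid(("size",), (x,), n.sum(axis=0), normalized=False)
    state = StableDistribution(dens.normalize(), lam, res, it, ok)
    if not ok:
        raise NoStableDistributionError(
            f"no stable distribution reached after {it} iterations", state=state)
    return state


# --------------------------------------------------------------------------
# sizer with septum-positioning noise
# --------------------------------------------------------------------------

def septum_kernel_truncnorm(cv: float, lo: float = 0.2, hi: float = 0.8,
                            n_points: int = 201):
    """Symmetric truncated-Gaussian septum kernel q(theta) about 1/2."""
    if cv == 0:
        return ("point", 0.5)
    sd = 0.5 * cv
    grid = np.linspace(lo, hi, n_points)
    a, b = (lo - 0.5) / sd, (hi - 0.5) / sd
    return grid, truncnorm.pdf(grid, a, b, loc=0.5, scale=sd)


def solve_with_septum_noise(B: DivisionRate, septum_kernel,
                            growth: GrowthLaw, cfg: SolverConfig
                            ) -> StableDistribution:
    """Sizer model with noisy septum positioning.

    A mother of size y splits into daughters of size theta*y and
    (1-theta)*y with theta drawn from the kernel q; the division gain term
    becomes 2 * integral B(y) q(x/y) n(y)/y dy, which reduces to
    4 B(2x) n(2x) for q concentrated at 1/2.  ``septum_kernel`` is
    ``("point", 0.5)`` or a pair ``(theta_grid, q_values)`` of a density on
    (0,1) symmetric about 1/2.
    """
    if B.index != "size":
        raise ValueError("septum-noise model requires a size rate")
    if (isinstance(septum_kernel, tuple) and isinstance(septum_kernel[0], str)
            and septum_kernel[0] == "point"):
        return solve_size_profile(B, growth, cfg)

    th, q = (np.asarray(septum_kernel[0], float),
             np.asarray(septum_kernel[1], float))
    if np.any(q < 0) or q.sum() <= 0:
        raise ValueError("septum kernel must be a nonnegative density")
    qn = q / np.trapezoid(q, th)
    mean_theta = float(np.trapezoid(th * qn, th))
    if abs(mean_theta - 0.5) > 1e-3:
        warnings.warn(f"septum kernel is asymmetric (mean {mean_theta:.3f}); "
                      "the two daughters are treated exchangeably",
                      stacklevel=2)
    tail = float(np.trapezoid(qn[(th < 0.05) | (th > 0.95)],
                              th[(th < 0.05) | (th > 0.95)])) if np.any(
                                  (th < 0.05) | (th > 0.95)) else 0.0
    if tail > 1e-6:
        raise ValueError("septum kernel has mass near 0 or 1 "
                         "(degenerate daughters)")

    x, dx, v_edges = _size_transport(cfg, growth)
    Bx = B(x)
    fac = cfg.renewal_factor   # 4 full, 2 sparse -> per-division factor below
    n_daughters = fac / 2.0    # 2 followed daughters (full) or 1 (sparse)
    # kernel matrix: gain_j = sum_k K[j,k] n_k, K[j,k] = c_k q(x_j/x_k)/x_k
    ratio = x[:, None] / x[None, :]
    qmat = np.interp(ratio, th, qn, left=0.0, right=0.0)
    K = qmat / x[None, :]
    col = K.sum(axis=0) * dx           # discrete integral of q over daughters
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(col[None, :] > 0, K / np.maximum(col[None, :], 1e-300),
                     0.0)
    K = K * (n_daughters * Bx[None, :] * dx)
    # columns now inject exactly n_daughters newborns per division event

    dt = _cfl_dt(cfg, float(v_edges.max()), with_age=False)
    cx = dt / dx
    decay = 1.0 / (1.0 + dt * Bx)

    def quad(n):
        return float(np.trapezoid(n, x))

    def step(n):
        gain = K @ n
        flux = v_edges[1:] * n
        div_x = np.empty_like(n)
        div_x[0] = flux[0]
        div_x[1:] = flux[1:] - flux[:-1]
        return (n - cx * div_x + dt * gain) * decay

    n0 = np.exp(-0.5 * ((x - 0.4 * x[-1]) / (0.15 * x[-1])) ** 2)
    n, lam, res, it, ok = _iterate(step, n0, quad, cfg, dt)
    dens = DensityGrid(("size",), (x,), n, normalized=True)
    state = StableDistribution(dens, lam, res, it, ok)
    if not ok:
        raise NoStableDistributionError(
            f"no stable distribution reached after {it} iterations", state=state)
    return state
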