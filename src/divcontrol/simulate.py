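"""Exact stochastic simulation of growing and dividing cell lineages.

Cells grow deterministically, each with its own growth rate drawn i.i.d. from
a truncated Gaussian, and divide stochastically under either *timer* control
(division rate B_a(a) indexed by age) or *sizer* control (B_s(x) indexed by
size).  Division times are sampled exactly by inverting the survival function
exp(-integral of B along the trajectory).  At division, a septum ratio theta
is drawn (truncated Gaussian around 1/2) and the daughters receive theta*x_d
and (1-theta)*x_d, so daughter birth lengths partition the mother's division
length to machine precision.

Two observation topologies are supported, mirroring the two classic
experimental designs: *full tree* (agar-pad microcolonies, every descendant
followed) and *sparse tree* (mother machine, one daughter per division
followed in each microchannel).

Observation convention: lengths are recorded on a per-cell acquisition grid
of spacing ``acquisition_dt`` anchored at birth, and division events are
realized on that grid (the continuously sampled division age is rounded to
the nearest frame, minimum one frame).  The mother's last frame shows the
division length and the daughters' first frames, at the same instant, show
their birth lengths.  This is the only convention under which the acquisition
grid, the mass-partition identity and the septum-ratio bookkeeping are all
exact simultaneously; it also reproduces the time-resolution limit of the
experiments, where the acquisition step is 5-8% of a division time.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .growthlaw import GrowthLaw
from .hazard import DivisionRate

__all__ = ["SimConfig", "simulate_population", "simulate_mother_machine",
           "apply_measurement_layer", "DivergentLifetimeError",
           "PopulationCapError"]


class DivergentLifetimeError(RuntimeError):
    """The hazard cannot accumulate enough mass to guarantee division."""


class PopulationCapError(RuntimeError):
    """Population exceeded the configured cap; carries the partial output."""

    def __init__(self, msg, partial_tracks=None):
        super().__init__(msg)
        self.partial_tracks = partial_tracks


@dataclass
class SimConfig:
    """Study conditions for a lineage simulation.

    Defaults emulate the agar-pad (full-tree) experimental condition: mean
    exponential growth rate 0.0274 min^-1 with 8% CV across cells, septum
    position CV 4% about symmetric division, 2-min acquisition frames.
    """

    control_law: str                      # 'timer' | 'sizer'
    division_rate: DivisionRate
    growth_law: GrowthLaw
    mean_rate: float = 0.0274             # min^-1
    rate_cv: float = 0.08
    septum_cv: float = 0.04
    topology: str = "full_tree"           # 'full_tree' | 'sparse_tree'
    duration: float | None = None         # observed span (min), full tree
    generations: int | None = None        # generations per channel, sparse
    n_channels: int = 100
    n_initial: int = 4                    # root cells, full tree
    initial_size: tuple = ("lognormal", 2.5, 0.15)   # (family, median, sigma_log)
    acquisition_dt: float = 2.0           # min
    length_noise_cv: float = 0.0
    division_time_noise_cv: float = 0.0
    burnin_generations: int = 5           # discarded before export (full tree)
    population_cap: int = 200_000
    seed: int = 0

    def __post_init__(self):
        if self.control_law not in ("timer", "sizer"):
            raise ValueError("control_law must be 'timer' or 'sizer'")
        want = "age" if self.control_law == "timer" else "size"
        if self.division_rate.index != want:
            raise ValueError(
                f"{self.control_law} control requires a {want}-indexed "
                f"division rate, got {self.division_rate.index!r}")
        if self.topology not in ("full_tree", "sparse_tree"):
            raise ValueError("topology must be 'full_tree' or 'sparse_tree'")
        for name in ("rate_cv", "septum_cv", "length_noise_cv",
                     "division_time_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.acquisition_dt <= 0:
            raise ValueError("acquisition_dt must be positive")
        if self.topology == "full_tree":
            if self.duration is None or self.duration <= 0:
                raise ValueError("full_tree simulation needs a positive duration")
        else:
            if self.generations is None or self.generations <= 0:
                raise ValueError("sparse_tree simulation needs generations > 0")


# --------------------------------------------------------------------------
# RNG plumbing: per-wave streams derived from the root seed so that the
# traversal order of the tree cannot change the results.
# --------------------------------------------------------------------------

def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=key))


def _draw_rates(rng, n, mean, cv):
    if cv == 0:
        return np.full(n, mean)
    lo = max(0.2, 1.0 - 3.0 * cv)
    hi = 1.0 + 3.0 * cv
    a, b = (lo - 1.0) / cv, (hi - 1.0) / cv
    return mean * truncnorm.rvs(a, b, loc=1.0, scale=cv, size=n,
                                random_state=rng)


def _draw_septa(rng, n, cv):
    if cv == 0:
        return np.full(n, 0.5)
    sd = 0.5 * cv
    a, b = (0.2 - 0.5) / sd, (0.8 - 0.5) / sd
    return truncnorm.rvs(a, b, loc=0.5, scale=sd, size=n, random_state=rng)


def _draw_initial_sizes(rng, n, spec):
    family = spec[0]
    if family == "lognormal":
        _, median, sigma = spec
        return median * np.exp(sigma * rng.standard_normal(n))
    if family == "fixed":
        return np.full(n, float(spec[1]))
    raise ValueError(f"unknown initial size distribution {family!r}")


# --------------------------------------------------------------------------
# exact lifetime sampling by survival-function inversion
# --------------------------------------------------------------------------

def _monotone_inverse(yq, y, x):
    """Invert a non-decreasing tabulated function y(x) at query points yq."""
    y = y + 1e-12 * np.arange(y.size)      # break plateaus for np.interp
    return np.interp(yq, y, x)


class _LifetimeSampler:
    """Samples continuous division ages given birth size and growth rate."""

    def __init__(self, config: SimConfig):
        self.cfg = config
        B = config.division_rate
        if config.control_law == "timer":
            ag = np.linspace(0.0, B.grid[-1], 4096)
            H = np.concatenate([[0.0], np.cumsum(
                0.5 * (B(ag[1:]) + B(ag[:-1])) * np.diff(ag))])
            self._ag, self._H = ag, H
        else:
            x_lo = max(1e-3, 0.02 * B.grid[1])
            x_hi = 4.0 * B.grid[-1]
            s = np.geomspace(x_lo, x_hi, 8192)
            integrand = B(s) / s
            G = np.concatenate([[0.0], np.cumsum(
                0.5 * (integrand[1:] + integrand[:-1]) * np.diff(s))])
            self._s, self._G = s, G

    def sample(self, x_b, v_i, u):
        E = -np.log(u)
        cfg = self.cfg
        B = cfg.division_rate
        if cfg.control_law == "timer":
            ag, H = self._ag, self._H
            tau = _monotone_inverse(E, H, ag)
            over = E > H[-1]
            if np.any(over):
                r = B.tail_rate
                if r <= 0:
                    raise DivergentLifetimeError(
                        "divergent lifetime: age hazard exhausted "
                        "(B identically zero beyond its table)")
                tau = np.where(over, ag[-1] + (E - H[-1]) / r, tau)
            return tau
        # sizer
        if cfg.growth_law.is_pure_exponential:
            s, G = self._s, self._G
            target = np.interp(x_b, s, G) + v_i * E
            x_d = _monotone_inverse(target, G, s)
            over = target > G[-1]
            if np.any(over):
                r = B.tail_rate
                if r <= 0:
                    raise DivergentLifetimeError(
                        "divergent lifetime: size hazard exhausted "
                        "(B identically zero beyond its table)")
                x_d = np.where(over, s[-1] * np.exp((target - G[-1]) / r), x_d)
            return np.log(x_d / x_b) / v_i
        return self._sample_sizer_numeric(x_b, v_i, E)

    def _sample_sizer_numeric(self, x_b, v_i, E):
        """Sizer with a capped growth law: integrate B along the trajectory."""
        cfg = self.cfg
        law, B = cfg.growth_law, cfg.division_rate
        h = cfg.acquisition_dt / 8.0
        n_steps = int(np.ceil(10.0 * np.log(2.0) / cfg.mean_rate / h))
        scale = v_i / cfg.mean_rate
        ladder = law.flow_ladder(x_b, h, n_steps, scale, substeps=1)
        rates = B(ladder)
        cum = np.zeros_like(ladder)
        cum[1:] = np.cumsum(0.5 * (rates[1:] + rates[:-1]) * h, axis=0)
        cols = np.arange(x_b.size)
        crossed = cum >= E[None, :]
        any_cross = crossed.any(axis=0)
        idx = np.maximum(np.where(any_cross, np.argmax(crossed, axis=0),
                                  n_steps), 1)
        c0 = cum[idx - 1, cols]
        c1 = cum[idx, cols]
        frac = np.clip((E - c0) / np.maximum(c1 - c0, 1e-300), 0.0, 1.0)
        tau = (idx - 1 + frac) * h
        missed = ~any_cross
        if np.any(missed):
            tail = rates[-1]
            if np.any(tail[missed] <= 0):
                raise DivergentLifetimeError(
                    "divergent lifetime: hazard never accumulates along the "
                    "capped trajectory")
            tau = np.where(missed,
                           n_steps * h + (E - cum[-1]) / np.maximum(tail, 1e-300),
                           tau)
        return tau


# --------------------------------------------------------------------------
# row emission
# --------------------------------------------------------------------------

def _emit_rows(birth_times, x_b, scale, n_frames, law, dt):
    """Render per-cell observation rows on birth-anchored frame grids.

    Returns (cell_index_repeat, times, lengths, ladder) where ladder[k, i]
    is cell i's length at frame k.
    """
    n = x_b.size
    max_k = int(n_frames.max()) if n else 0
    ladder = law.flow_ladder(x_b, dt, max_k, scale)
    counts = n_frames + 1
    cell_rep = np.repeat(np.arange(n), counts)
    offs = np.concatenate([[0], np.cumsum(counts)])[:-1]
    frame = np.arange(int(counts.sum())) - np.repeat(offs, counts)
    times = birth_times[cell_rep] + frame * dt
    lengths = ladder[frame, cell_rep]
    return cell_rep, times, lengths, ladder


def _assemble_table(chunks, meta, t_export_from, cap_hit, config):
    """Relabel internal ids to sequential ones and build the DataFrame."""
    internal = np.array([m[0] for m in meta], dtype=np.int64)
    parent_internal = np.array([m[1] for m in meta], dtype=np.int64)
    birth = np.array([m[2] for m in meta], dtype=float)
    keep = birth >= t_export_from - 1e-9
    order = np.lexsort((internal[keep], birth[keep]))
    kept_internal = internal[keep][order]
    new_id = {int(iid): i + 1 for i, iid in enumerate(kept_internal)}
    rows_id, rows_t, rows_l = [], [], []
    for iid, times, lengths in chunks:
        if int(iid) in new_id:
            rows_id.append(np.full(times.size, new_id[int(iid)], dtype=np.int64))
            rows_t.append(times)
            rows_l.append(lengths)
    parent_map = {int(i): int(p) for i, p in zip(internal, parent_internal)}
    pid = np.empty(kept_internal.size, dtype=object)
    for i, iid in enumerate(kept_internal):
        p = parent_map[int(iid)]
        pid[i] = new_id.get(p, None) if p >= 0 else None
    df = pd.DataFrame({
        "cell_id": np.concatenate(rows_id) if rows_id else np.array([], dtype=np.int64),
        "time_min": np.concatenate(rows_t) if rows_t else np.array([]),
        "length_um": np.concatenate(rows_l) if rows_l else np.array([]),
    })
    pmap = {new_id[int(iid)]: pid[i] for i, iid in enumerate(kept_internal)}
    df.insert(1, "parent_id", df["cell_id"].map(pmap).astype("Int64"))
    df = df.sort_values(["cell_id", "time_min"], kind="mergesort",
                        ignore_index=True)
    if cap_hit:
        raise PopulationCapError(
            f"population exceeded cap of {config.population_cap}; "
            "partial output attached", partial_tracks=df)
    return df


# --------------------------------------------------------------------------
# full-tree simulation
# --------------------------------------------------------------------------

def simulate_population(config: SimConfig) -> pd.DataFrame:
    """Exact event-driven full-tree simulation; returns a TrackTable.

    Roots start at t=0; the first ``burnin_generations`` doubling times are
    discarded before export (cells *born* during burn-in are dropped, their
    children become roots), after which ``duration`` minutes are observed.
    Identical (config, seed) gives a byte-identical table.
    """
    if config.topology != "full_tree":
        raise ValueError("simulate_population requires topology='full_tree'")
    dt = config.acquisition_dt
    sampler = _LifetimeSampler(config)
    t_burn = config.burnin_generations * np.log(2.0) / config.mean_rate
    t_end = t_burn + config.duration

    rng0 = _rng(config.seed, 0, 0)
    n0 = config.n_initial
    ids = (np.arange(n0, dtype=np.int64) << 48) | 1
    x_b = _draw_initial_sizes(rng0, n0, config.initial_size)
    # founders start unsynchronized (staggered over one doubling time, as in
    # a real inoculum); otherwise the whole colony rings coherently at the
    # generation period for many generations
    birth = rng0.uniform(0.0, np.log(2.0) / config.mean_rate, n0)
    birth = np.round(birth / dt) * dt
    parent = np.full(n0, -1, dtype=np.int64)

    chunks, meta = [], []
    cap_hit = False
    gen = 0
    total_cells = 0
    while ids.size:
        if gen > 80:
            raise RuntimeError("generation limit exceeded (runaway tree)")
        order = np.argsort(ids)
        ids, x_b, birth, parent = (ids[order], x_b[order], birth[order],
                                   parent[order])
        n = ids.size
        total_cells += n
        rng = _rng(config.seed, 1, gen)
        v_i = _draw_rates(rng, n, config.mean_rate, config.rate_cv)
        u = rng.random(n)
        theta = _draw_septa(rng, n, config.septum_cv)
        tau = sampler.sample(x_b, v_i, u)
        a_d = np.maximum(dt, np.round(tau / dt) * dt)
        div_time = birth + a_d
        divides = div_time <= t_end + 1e-9
        k_div = np.rint(a_d / dt).astype(int)
        k_cut = np.floor((t_end - birth) / dt + 1e-9).astype(int)
        n_frames = np.where(divides, k_div, np.maximum(k_cut, 0))
        scale = v_i / config.mean_rate
        cell_rep, times, lengths, ladder = _emit_rows(
            birth, x_b, scale, n_frames, config.growth_law, dt)
        bounds = np.searchsorted(cell_rep, np.arange(n + 1))
        for i in range(n):
            sl = slice(bounds[i], bounds[i + 1])
            chunks.append((ids[i], times[sl], lengths[sl]))
            meta.append((ids[i], parent[i], birth[i]))
        # spawn daughters of dividing cells
        div = np.flatnonzero(divides)
        if div.size == 0:
            break
        x_d = ladder[n_frames[div], div]
        d1 = theta[div] * x_d
        d2 = x_d - d1
        child_ids = np.concatenate([ids[div] * 2, ids[div] * 2 + 1])
        child_parent = np.concatenate([ids[div], ids[div]])
        child_birth = np.concatenate([div_time[div], div_time[div]])
        child_x = np.concatenate([d1, d2])
        if total_cells + child_ids.size > config.population_cap:
            cap_hit = True
            break
        ids, parent, birth, x_b = child_ids, child_parent, child_birth, child_x
        gen += 1

    return _assemble_table(chunks, meta, t_burn, cap_hit, config)


# --------------------------------------------------------------------------
# mother-machine (sparse-tree) simulation
# --------------------------------------------------------------------------

def simulate_mother_machine(config: SimConfig) -> pd.DataFrame:
    """Sparse-tree simulation: one line of descent per microchannel.

    Each of ``n_channels`` channels follows a single lineage for
    ``generations`` complete cycles; at each division one daughter is
    retained uniformly at random.  Frames are anchored at each cell's birth
    with spacing ``acquisition_dt`` (channels are asynchronous, as in the
    microfluidic experiment).
    """
    if config.topology != "sparse_tree":
        raise ValueError("simulate_mother_machine requires topology='sparse_tree'")
    dt = config.acquisition_dt
    sampler = _LifetimeSampler(config)
    C = config.n_channels
    G = int(config.generations)
    if C * (G + 1) > config.population_cap:
        raise PopulationCapError(
            f"n_channels*generations exceeds population cap "
            f"{config.population_cap}")

    rng0 = _rng(config.seed, 0, 0)
    x_b = _draw_initial_sizes(rng0, C, config.initial_size)
    birth = np.zeros(C)
    chan = np.arange(C, dtype=np.int64)

    chunks, meta = [], []
    for g in range(G):
        rng = _rng(config.seed, 1, g)
        v_i = _draw_rates(rng, C, config.mean_rate, config.rate_cv)
        u = rng.random(C)
        theta = _draw_septa(rng, C, config.septum_cv)
        pick_first = rng.random(C) < 0.5
        tau = sampler.sample(x_b, v_i, u)
        a_d = np.maximum(dt, np.round(tau / dt) * dt)
        n_frames = np.rint(a_d / dt).astype(int)
        scale = v_i / config.mean_rate
        cell_rep, times, lengths, ladder = _emit_rows(
            birth, x_b, scale, n_frames, config.growth_law, dt)
        ids = (chan << 32) | (g + 1)
        parent = (chan << 32) | g if g > 0 else np.full(C, -1, dtype=np.int64)
        bounds = np.searchsorted(cell_rep, np.arange(C + 1))
        for i in range(C):
            sl = slice(bounds[i], bounds[i + 1])
            chunks.append((ids[i], times[sl], lengths[sl]))
            meta.append((ids[i], parent[i], birth[i]))
        x_d = ladder[n_frames, np.arange(C)]
        d1 = theta * x_d
        d2 = x_d - d1
        x_b = np.where(pick_first, d1, d2)
        birth = birth + a_d

    return _assemble_table(chunks, meta, 0.0, False, config)


# --------------------------------------------------------------------------
# measurement layer
# --------------------------------------------------------------------------

def apply_measurement_layer(tracks: pd.DataFrame, config: SimConfig
                            ) -> pd.DataFrame:
    """Add measurement noise to a noiseless track table.

    Division-time noise: each division event is shifted by a Gaussian offset
    with SD = ``division_time_noise_cv`` x (population mean cycle duration),
    snapped to the acquisition grid; the boundary frames are reattributed
    between mother and daughters so the table stays a valid track table
    (misdetection of the septum by a few frames, as in the experiments).
    Offsets that would make a cycle non-positive are redrawn; if more than 1%
    of cycles cannot accommodate their offset an error is raised.

    Length noise: every length is multiplied by (1 + eps) with eps a
    truncated Gaussian (SD ``length_noise_cv``, truncated at 4 SD) so lengths
    stay positive for CVs up to 10% and beyond.
    """
    df = tracks.sort_values(["cell_id", "time_min"], kind="mergesort",
                            ignore_index=True)
    dt = config.acquisition_dt
    rng = _rng(config.seed, 2, 0)

    if config.division_time_noise_cv > 0:
        cells = {}
        for cid, grp in df.groupby("cell_id", sort=True):
            cells[int(cid)] = [grp["time_min"].to_numpy().copy(),
                               grp["length_um"].to_numpy().copy()]
        parent_of = (df.drop_duplicates("cell_id")
                       .set_index("cell_id")["parent_id"])
        children = {}
        for cid, pid in parent_of.items():
            if pd.notna(pid):
                children.setdefault(int(pid), []).append(int(cid))
        mothers = sorted(children, key=lambda c: (cells[c][0][-1], c))
        cycle_spans = [cells[m][0][-1] - cells[m][0][0] for m in mothers]
        mean_cycle = float(np.mean(cycle_spans))
        sd = config.division_time_noise_cv * mean_cycle
        theta_hat = {}
        for m in mothers:
            x_div = cells[m][1][-1]
            for c in children[m]:
                theta_hat[c] = cells[c][1][0] / x_div

        n_first_fail = 0
        for m in mothers:
            kids = children[m]
            k = 0
            for attempt in range(50):
                delta = rng.normal(0.0, sd)
                k_try = int(np.rint(delta / dt))
                mt = cells[m][0]
                ok = (mt.size + k_try) >= 2
                for c in kids:
                    need = 2 if c in children else 1
                    ok = ok and (cells[c][0].size - k_try) >= need
                if attempt == 0 and not ok:
                    # a first-draw offset this cycle cannot accommodate
                    n_first_fail += 1
                if k_try == 0:
                    k = 0
                    break
                if ok:
                    k = k_try
                    break
            else:
                k = 0
            if k == 0:
                continue
            mt, ml = cells[m]
            if k > 0:
                t_new = mt[-1] + dt * np.arange(1, k + 1)
                seen = np.zeros(k)
                for c in kids:
                    seen += cells[c][1][:k]
                    cells[c][0] = cells[c][0][k:]
                    cells[c][1] = cells[c][1][k:]
                if len(kids) == 1:   # sparse tree: infer the unseen sister
                    seen = seen / theta_hat[kids[0]]
                cells[m][0] = np.concatenate([mt, t_new])
                cells[m][1] = np.concatenate([ml, seen])
            else:
                kk = -k
                t_cut = mt[-kk:]
                l_cut = ml[-kk:]
                cells[m][0] = mt[:-kk]
                cells[m][1] = ml[:-kk]
                for c in kids:
                    cells[c][0] = np.concatenate([t_cut, cells[c][0]])
                    cells[c][1] = np.concatenate([theta_hat[c] * l_cut,
                                                  cells[c][1]])
        if n_first_fail > 0.01 * max(1, len(mothers)):
            raise ValueError(
                "division-time noise too large: more than 1% of cycles "
                "would become non-positive")
        rows_id, rows_t, rows_l = [], [], []
        for cid in sorted(cells):
            t, l = cells[cid]
            rows_id.append(np.full(t.size, cid, dtype=np.int64))
            rows_t.append(t)
            rows_l.append(l)
        out = pd.DataFrame({
            "cell_id": np.concatenate(rows_id),
            "time_min": np.concatenate(rows_t),
            "length_um": np.concatenate(rows_l),
        })
        pmap = parent_of.to_dict()
        out.insert(1, "parent_id", out["cell_id"].map(pmap).astype("Int64"))
        df = out

    if config.length_noise_cv > 0:
        cv = config.length_noise_cv
        eps = truncnorm.rvs(-4.0, 4.0, loc=0.0, scale=cv,
                            size=len(df), random_state=rng)
        df = df.copy()
        df["length_um"] = df["length_um"] * (1.0 + eps)

    return df
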