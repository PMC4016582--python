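"""Single-cell growth laws v(x).

A growth law gives the deterministic rate of length increase dx/dt = v(x) of a
single cell of length x.  In the central size range [x_min, x_max] growth is
exponential, v(x) = v * x.  Outside that range the behaviour of rare, unusually
small or large cells is unknown and is replaced by a configurable *cap*:
``none`` (exponential everywhere), ``constant`` (the rate freezes at its value
at the threshold, i.e. linear growth in time), ``linear`` (affine continuation
with a given slope) or ``polynomial`` (an explicit polynomial p(x), clamped at
zero so the rate never turns negative).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GrowthLaw"]

_CAP_KINDS = {"none", "constant", "linear", "polynomial"}


@dataclass(frozen=True)
class GrowthLaw:
    """Piecewise growth law: exponential core with configurable caps.

    Parameters
    ----------
    v : float
        Core exponential rate (min^-1); in the core range v(x) = v * x.
    x_min, x_max : float
        Thresholds (µm) delimiting the exponential range.  Defaults span
        everything, i.e. pure exponential growth.
    cap_below, cap_above : tuple
        Cap specification outside the core range.  One of ``("none",)``,
        ``("constant",)``, ``("linear", slope)`` or ``("polynomial", coeffs)``
        with ``coeffs`` highest-order-first (numpy polyval convention).
    clamp_at_zero : bool
        If True (default), v(x) = max(p(x), 0) for polynomial caps.
    """

    v: float
    x_min: float = 0.0
    x_max: float = float("inf")
    cap_below: tuple = ("none",)
    cap_above: tuple = ("none",)
    clamp_at_zero: bool = True

    def __post_init__(self):
        if self.v <= 0:
            raise ValueError("core growth rate v must be positive")
        if not (0 <= self.x_min <= self.x_max):
            raise ValueError("need 0 <= x_min <= x_max")
        for cap in (self.cap_below, self.cap_above):
            if cap[0] not in _CAP_KINDS:
                raise ValueError(f"unknown cap kind {cap[0]!r}")

    # ---------------------------------------------------------------- factory
    @classmethod
    def exponential(cls, v: float) -> "GrowthLaw":
        """Pure exponential growth v(x) = v*x on the whole size axis."""
        return cls(v=v)

    @classmethod
    def capped_constant(cls, v: float, x_min: float, x_max: float) -> "GrowthLaw":
        """Exponential core, rate frozen at the thresholds outside it."""
        return cls(v=v, x_min=x_min, x_max=x_max,
                   cap_below=("constant",), cap_above=("constant",))

    @classmethod
    def from_polynomial(cls, v: float, x_min: float, x_max: float,
                        coeffs) -> "GrowthLaw":
        """Exponential core with v(x) = max(p(x), 0) outside [x_min, x_max]."""
        coeffs = tuple(float(c) for c in coeffs)
        return cls(v=v, x_min=x_min, x_max=x_max,
                   cap_below=("polynomial", coeffs),
                   cap_above=("polynomial", coeffs))

    # ------------------------------------------------------------- evaluation
    @property
    def is_pure_exponential(self) -> bool:
        return (self.x_min <= 0 and np.isinf(self.x_max)) or (
            self.cap_below[0] == "none" and self.cap_above[0] == "none")

    def _cap_value(self, cap: tuple, x: np.ndarray, threshold: float) -> np.ndarray:
        kind = cap[0]
        if kind == "none":
            return self.v * x
        if kind == "constant":
            return np.full_like(x, self.v * threshold)
        if kind == "linear":
            slope = cap[1]
            return self.v * threshold + slope * (x - threshold)
        # polynomial
        val = np.polyval(cap[1], x)
        if self.clamp_at_zero:
            val = np.maximum(val, 0.0)
        return val

    def rate(self, x, scale: float | np.ndarray = 1.0) -> np.ndarray:
        """Growth rate v(x) (µm/min); ``scale`` multiplies the whole law.

        ``scale`` carries per-cell growth-rate variability: a cell with
        individual rate v_i uses scale = v_i / v.
        """
        x = np.asarray(x, dtype=float)
        out = self.v * x
        lo = x < self.x_min
        hi = x > self.x_max
        if np.any(lo):
            out = np.where(lo, self._cap_value(self.cap_below, x, self.x_min), out)
        if np.any(hi):
            out = np.where(hi, self._cap_value(self.cap_above, x, self.x_max), out)
        out = np.maximum(out, 0.0)
        return out * scale

    def __call__(self, x, scale=1.0):
        return self.rate(x, scale)

    # ------------------------------------------------------------------ flow
    def flow(self, x0, t, scale=1.0, dt_max: float = 0.25):
        """Integrate dx/dt = scale*v(x) from x0 for time t (t scalar or array).

        Pure-exponential laws use the closed form; otherwise classical RK4
        with fixed substeps no longer than ``dt_max`` minutes.
        """
        x0 = np.asarray(x0, dtype=float)
        t = np.asarray(t, dtype=float)
        scale = np.asarray(scale, dtype=float)
        if self.is_pure_exponential:
            return x0 * np.exp(self.v * scale * t)
        tmax = float(np.max(t)) if t.size else 0.0
        n_steps = max(1, int(np.ceil(tmax / dt_max)))
        h = tmax / n_steps if tmax > 0 else 0.0
        x = np.broadcast_to(x0, np.broadcast_shapes(x0.shape, t.shape, scale.shape)).copy()
        t_b = np.broadcast_to(t, x.shape)
        remaining = t_b.copy()
        for _ in range(n_steps):
            step = np.minimum(remaining, h)
            active = step > 0
            if not np.any(active):
                break
            x_new = _rk4_step(self, x, step, scale)
            x = np.where(active, x_new, x)
            remaining = remaining - step
        return x

    def flow_ladder(self, x0, dt: float, n_steps: int, scale=1.0,
                    substeps: int = 4) -> np.ndarray:
        """Trajectory matrix x(k*dt) for k = 0..n_steps (shape (n_steps+1, n))."""
        x0 = np.asarray(x0, dtype=float)
        scale = np.asarray(scale, dtype=float)
        if self.is_pure_exponential:
            k = np.arange(n_steps + 1)[:, None]
            return x0[None, :] * np.exp(self.v * scale[None, :] * k * dt)
        out = np.empty((n_steps + 1, x0.size))
        out[0] = x0
        x = x0.copy()
        h = dt / substeps
        for k in range(1, n_steps + 1):
            for _ in range(substeps):
                x = _rk4_step(self, x, h, scale)
            out[k] = x
        return out


def _rk4_step(law: GrowthLaw, x, h, scale):
    k1 = law.rate(x, scale)
    k2 = law.rate(x + 0.5 * h * k1, scale)
    k3 = law.rate(x + 0.5 * h * k2, scale)
    k4 = law.rate(x + h * k3, scale)
    return x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
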