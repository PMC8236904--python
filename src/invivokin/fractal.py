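"""Fractal (diffusion-limited) kinetics: power-law rate constants.

Under diffusion limitation — e.g. reactants confined to a channel or a
supramolecular enzyme assembly — the law of mass action breaks down and
the bimolecular rate "constant" decays in time as k(t) = k0*t**(-h),
where 0 <= h < 1 reflects the fractal dimension of the medium (h = 0
recovers classical kinetics).  Eliminating time from the integrated decay
of a dimerisation A + A -> product yields a time-independent rate law
with an elevated effective reaction order,

    rate = -k_star * A**alpha,    alpha = 2 + h/(1 - h),

so an intrinsically bimolecular step behaves as order alpha > 2.  Applied
to substrate binding in an enzyme-substrate scheme, the same argument
turns v = vmax*S/(K_M + S) into an apparent Hill law
v = vmax*S**n/(K_M* + S**n) — cooperativity without allostery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import DataError, _check_positive

__all__ = [
    "FractalParams",
    "KineticTrace",
    "fractal_decay_closed_form",
    "fractal_decay_numeric",
    "effective_order",
    "effective_order_from_trace",
    "fractal_enzyme_rate",
]


@dataclass(frozen=True)
class FractalParams:
    """Rate prefactor k0 and fractal exponent h of k(t) = k0*t**(-h)."""

    k0: float
    h: float

    def __post_init__(self) -> None:
        _check_positive(k0=self.k0)
        if not 0 <= self.h < 1:
            raise ValueError(f"fractal exponent h must be in [0, 1), got {self.h}")

    @property
    def alpha(self) -> float:
        """Effective reaction order of the dimerisation, 2 + h/(1-h)."""
        return effective_order(self.h)

    @property
    def k_star(self) -> float:
        """Time-independent apparent rate constant in rate = -k_star*A**alpha.

        k_star = (1-h)**(h/(h-1)) * k0**(1/(1-h)); equals k0 at h = 0.
        """
        if self.h == 0:
            return self.k0
        one_minus_h = 1.0 - self.h
        return one_minus_h ** (self.h / (self.h - 1.0)) * self.k0 ** (1.0 / one_minus_h)


@dataclass(frozen=True)
class KineticTrace:
    """A sampled kinetic time course (time, concentration-or-signal)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D of equal length")
        if len(t) < 4:
            raise ValueError("a kinetic trace needs at least 4 points")
        if np.any(t < 0) or not np.all(np.diff(t) > 0):
            raise ValueError("times must be non-negative and strictly increasing")


def effective_order(h: float) -> float:
    """Effective reaction order alpha = 2 + h/(1-h) of a fractal dimerisation."""
    if not 0 <= h < 1:
        raise ValueError(f"fractal exponent h must be in [0, 1), got {h}")
    return 2.0 + h / (1.0 - h)


def fractal_decay_closed_form(params: FractalParams, t):
    """Long-time asymptote A(t) = (1-h) / (k0 * t**(1-h)).

    Valid once the initial concentration term 1/A0 is negligible; at
    h = 0 this is the classical second-order 1/(k0*t) decay.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    out = (1.0 - params.h) / (params.k0 * t ** (1.0 - params.h))
    return out if out.ndim else float(out)


def fractal_decay_numeric(
    a0: float, params: FractalParams, t_grid
) -> KineticTrace:
    """Exact decay A(t) of dA/dt = -k0*t**(-h)*A**2 from A(t0) = a0.

    The equation is separable; in quadrature form
    1/A(t) = 1/a0 + k0*(t**(1-h) - t0**(1-h))/(1-h), with t0 the first
    grid time (must be > 0 when h > 0 because the rate constant diverges
    at t = 0).
    """
    _check_positive(a0=a0)
    t = np.asarray(t_grid, dtype=float)
    if params.h > 0 and t[0] <= 0:
        raise ValueError("t_grid must start at t0 > 0 when h > 0")
    if t[0] < 0:
        raise ValueError("t_grid must be non-negative")
    one_minus_h = 1.0 - params.h
    integral = params.k0 * (t**one_minus_h - t[0] ** one_minus_h) / one_minus_h
    return KineticTrace(times=t, values=1.0 / (1.0 / a0 + integral))


def effective_order_from_trace(
    trace: KineticTrace, late_fraction: float = 0.5
) -> float:
    """Estimate the effective order alpha from a decaying kinetic trace.

    Resamples the late-time window (last ``late_fraction`` of the time
    span, log-spaced) where the power-law asymptote holds, differentiates
    by central differences, and regresses ln(-dA/dt) on ln A.  The slope
    is the effective order; on a fractal decay with exponent h it matches
    2 + h/(1-h).
    """
    if len(trace.times) < 10:
        raise DataError("need at least 10 points to estimate an effective order")
    if not np.all(np.diff(trace.values) < 0):
        raise DataError("trace must be strictly decreasing")
    if np.any(trace.values <= 0):
        raise DataError("trace values must be positive")
    t_lo = trace.times[-1] * (trace.times[0] / trace.times[-1]) ** late_fraction
    t_lo = max(t_lo, trace.times[0])
    n_pts = max(len(trace.times) // 2, 10)
    t_res = np.geomspace(max(t_lo, trace.times[0]), trace.times[-1], n_pts)
    a_res = np.interp(t_res, trace.times, trace.values)
    rate = -np.gradient(a_res, t_res)
    keep = rate > 0
    if keep.sum() < 5:
        raise DataError("too few points with positive decay rate")
    slope, _ = np.polyfit(np.log(a_res[keep]), np.log(rate[keep]), 1)
    return float(slope)


def fractal_enzyme_rate(s, e0: float, k2: float, km_star: float, exponent: float):
    """Apparent Hill rate law of a diffusion-limited enzyme.

    v = k2*e0*s**n / (km_star + s**n), where km_star is the apparent
    Michaelis constant (units concentration**n) and n the Hill-coefficient
    analog set by the fractal dimension of the substrate's medium.
    exponent = 1 reduces to MM with K_M = km_star.
    """
    _check_positive(e0=e0, k2=k2, km_star=km_star, exponent=exponent)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate concentration must be >= 0")
    sn = s**exponent
    out = k2 * e0 * sn / (km_star + sn)
    return out if out.ndim else float(out)
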