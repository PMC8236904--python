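"""Steady-state theory for two consecutive enzymes in a metabolic pathway.

At steady state the flux producing an intermediate metabolite equals the
flux consuming it.  For a chain ``S1 --E1--> S2 --E2--> S3`` where both
enzymes obey Michaelis-Menten (MM) kinetics and product rebinding is
negligible, flux balance gives a closed-form hyperbolic dependence of the
intermediate pool on its precursor,

    S2 = A*S1 / (B + C*S1),
    A = k2*K_M2*E10,  B = k4*K_M1*E20,  C = k4*E20 - k2*E10.

When the enzymes are Hill-like with exponents ``m`` (upstream) and ``n``
(downstream) the same balance yields

    S2 = (A*S1**m / (B + C*S1**m)) ** (1/n),

so the *apparent* cooperativity of the S2-vs-S1 relationship at low S1 is
``m/n``: a steady-state metabolite scatter plot is sigmoidal only when the
producing enzyme is more cooperative than the consuming one.

The full reversible balance (product rebinding through the reverse
Michaelis constants K_M2', K_M3) has no closed form and is solved
numerically on its monotone flux residual.

All functions accept concentrations in either absolute (e.g. uM) or
relative (reference-normalised) units; only ratios and curve shapes are
interpreted, and containers carry a unit tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "NoSteadyStateError",
    "DataError",
    "EnzymeParams",
    "TwoEnzymeChain",
    "ChainCoefficients",
    "SteadyStateCurve",
    "mm_rate",
    "hill_rate",
    "chain_coefficients",
    "chain_steady_state_mm",
    "chain_steady_state_hill",
    "chain_steady_state_reversible",
    "apparent_hill_exponent",
    "loglog_slopes",
    "mutant_ratio_scan",
]


class NoSteadyStateError(RuntimeError):
    """Upstream flux meets or exceeds downstream capacity: no finite S2."""


class DataError(ValueError):
    """Input curve/trace violates the preconditions of an estimator."""


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{name} must be > 0, got {value!r}")


def mm_rate(s, vmax: float, km: float):
    """Michaelis-Menten rate v = vmax*s/(km + s).

    Parameters
    ----------
    s : float or array-like
        Substrate concentration, >= 0.
    vmax : float
        Limiting rate (k_cat * total enzyme), > 0.
    km : float
        Michaelis constant (substrate at half-maximal rate), > 0.
    """
    _check_positive(vmax=vmax, km=km)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate concentration must be >= 0")
    out = vmax * s / (km + s)
    return out if out.ndim else float(out)


def hill_rate(s, vmax: float, k_half: float, exponent: float):
    """Hill rate v = vmax*s**n / (k_half**n + s**n).

    ``k_half`` is the half-saturation concentration; ``exponent`` (the Hill
    coefficient) = 1 reduces exactly to :func:`mm_rate`.
    """
    _check_positive(vmax=vmax, k_half=k_half, exponent=exponent)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate concentration must be >= 0")
    sn = s**exponent
    out = vmax * sn / (k_half**exponent + sn)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class EnzymeParams:
    """Kinetic parameters of one enzyme.

    Attributes
    ----------
    e_total : float
        Total enzyme concentration (free + complexed), arbitrary units.
    k_cat : float
        Turnover rate constant (1/time).
    k_m : float
        Half-saturation substrate concentration.  For a Hill enzyme this is
        the half-saturation point; the apparent constant that appears next
        to ``s**exponent`` in the rate law is ``k_m**exponent``.
    exponent : float
        Hill coefficient (1 = Michaelis-Menten).
    """

    e_total: float
    k_cat: float
    k_m: float
    exponent: float = 1.0

    def __post_init__(self) -> None:
        _check_positive(
            e_total=self.e_total, k_cat=self.k_cat, k_m=self.k_m, exponent=self.exponent
        )

    @property
    def vmax(self) -> float:
        return self.k_cat * self.e_total

    @property
    def k_m_apparent(self) -> float:
        """Apparent constant K* in the form v = vmax*s**n/(K* + s**n)."""
        return self.k_m**self.exponent

    def rate(self, s):
        return hill_rate(s, self.vmax, self.k_m, self.exponent)


@dataclass(frozen=True)
class TwoEnzymeChain:
    """Ordered pair of enzymes acting on consecutive metabolites.

    The chain is irreversible when the reverse binding constants are unset;
    setting ``reverse_km_upstream_product`` (K_M2' : affinity of E1 for its
    product S2) and ``reverse_km_downstream_product`` (K_M3 : affinity of E2
    for its product S3) enables the full reversible flux balance.
    ``reverse_kcats`` holds (k_-1, k_-3), the reverse turnover rates; they
    default to 0 (product rebinds but carries no reverse flux).
    ``downstream_product`` is the steady-state S3 pool (default 0: sink).
    """

    upstream: EnzymeParams
    downstream: EnzymeParams
    reverse_km_upstream_product: float | None = None
    reverse_km_downstream_product: float | None = None
    downstream_product: float = 0.0
    reverse_kcats: tuple[float, float] = (0.0, 0.0)
    unit: str = "relative"

    def __post_init__(self) -> None:
        for name in ("reverse_km_upstream_product", "reverse_km_downstream_product"):
            value = getattr(self, name)
            if value is not None:
                _check_positive(**{name: value})
        if self.downstream_product < 0:
            raise ValueError("downstream_product must be >= 0")
        if any(k < 0 for k in self.reverse_kcats):
            raise ValueError("reverse_kcats must be >= 0")

    @property
    def is_reversible(self) -> bool:
        return (
            self.reverse_km_upstream_product is not None
            and self.reverse_km_downstream_product is not None
        )


@dataclass(frozen=True)
class ChainCoefficients:
    """Coefficients (A, B, C) of the closed-form steady-state relationship."""

    a_coef: float
    b_coef: float
    c_coef: float

    def __post_init__(self) -> None:
        _check_positive(a_coef=self.a_coef, b_coef=self.b_coef)

    @property
    def critical_s1(self) -> float:
        """Upstream concentration at which downstream capacity is exhausted.

        Finite only when C < 0 (upstream limiting rate exceeds downstream).
        """
        if self.c_coef >= 0:
            return np.inf
        return -self.b_coef / self.c_coef


@dataclass(frozen=True)
class SteadyStateCurve:
    """Tabulated steady-state product-vs-substrate relationship."""

    s1_values: np.ndarray
    s2_values: np.ndarray
    unit: str = "relative"

    def __post_init__(self) -> None:
        s1 = np.asarray(self.s1_values, dtype=float)
        s2 = np.asarray(self.s2_values, dtype=float)
        object.__setattr__(self, "s1_values", s1)
        object.__setattr__(self, "s2_values", s2)
        if s1.shape != s2.shape or s1.ndim != 1:
            raise ValueError("s1_values and s2_values must be 1-D of equal length")
        if not np.all(np.diff(s1) > 0):
            raise ValueError("s1_values must be strictly increasing")
        if np.any(s1 <= 0):
            raise ValueError("s1_values must be positive")
        if np.any(s2 < 0):
            raise ValueError("s2_values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"s1": self.s1_values, "s2": self.s2_values})


def chain_coefficients(chain: TwoEnzymeChain) -> ChainCoefficients:
    """(A, B, C) of S2 = A*S1**m/(B + C*S1**m), from the chain parameters.

    A = k2*K_M2*E10, B = k4*K_M1*E20, C = k4*E20 - k2*E10, with the
    apparent constants ``k_m**exponent`` standing in for K_M when an
    enzyme is Hill-like.
    """
    up, down = chain.upstream, chain.downstream
    return ChainCoefficients(
        a_coef=up.vmax * down.k_m_apparent,
        b_coef=down.vmax * up.k_m_apparent,
        c_coef=down.vmax - up.vmax,
    )


def _checked_denominator(coefs: ChainCoefficients, s1_pow) -> np.ndarray:
    denom = coefs.b_coef + coefs.c_coef * s1_pow
    if np.any(denom <= 0):
        raise NoSteadyStateError(
            "upstream flux meets or exceeds downstream capacity; no steady state "
            f"for s1 at or beyond the critical value {coefs.critical_s1:.6g} "
            "(in the upstream-exponent power scale)"
        )
    return denom


def chain_steady_state_mm(chain: TwoEnzymeChain, s1):
    """Closed-form steady-state S2 for an irreversible MM chain.

    S2 = A*s1/(B + C*s1).  Raises :class:`NoSteadyStateError` when
    B + C*s1 <= 0, i.e. the upstream flux at s1 reaches the downstream
    limiting rate.
    """
    if chain.upstream.exponent != 1 or chain.downstream.exponent != 1:
        raise ValueError("chain_steady_state_mm requires both exponents = 1")
    coefs = chain_coefficients(chain)
    s1 = np.asarray(s1, dtype=float)
    if np.any(s1 < 0):
        raise ValueError("s1 must be >= 0")
    denom = _checked_denominator(coefs, s1)
    out = coefs.a_coef * s1 / denom
    return out if out.ndim else float(out)


def chain_steady_state_hill(chain: TwoEnzymeChain, s1):
    """Steady-state S2 for an irreversible chain of Hill enzymes.

    S2 = (A*s1**m / (B + C*s1**m))**(1/n); reduces to
    :func:`chain_steady_state_mm` at m = n = 1.
    """
    m = chain.upstream.exponent
    n = chain.downstream.exponent
    coefs = chain_coefficients(chain)
    s1 = np.asarray(s1, dtype=float)
    if np.any(s1 < 0):
        raise ValueError("s1 must be >= 0")
    s1m = s1**m
    denom = _checked_denominator(coefs, s1m)
    out = (coefs.a_coef * s1m / denom) ** (1.0 / n)
    return out if out.ndim else float(out)


def _flux_residual(chain: TwoEnzymeChain, s1: float, s2: float) -> float:
    """Net production flux of S2 under the full reversible balance.

    E10*(k2*S1/K_M1 - k_-1*S2/K_M2') / (1 + S1/K_M1 + S2/K_M2')
      - E20*(k4*S2/K_M2 - k_-3*S3/K_M3) / (1 + S2/K_M2 + S3/K_M3)

    Strictly decreasing in S2, so any sign-changing bracket is valid.
    """
    up, down = chain.upstream, chain.downstream
    km2p = chain.reverse_km_upstream_product
    km3 = chain.reverse_km_downstream_product
    k_1, k_3 = chain.reverse_kcats
    s3 = chain.downstream_product
    production = (
        up.e_total
        * (up.k_cat * s1 / up.k_m - k_1 * s2 / km2p)
        / (1.0 + s1 / up.k_m + s2 / km2p)
    )
    consumption = (
        down.e_total
        * (down.k_cat * s2 / down.k_m - k_3 * s3 / km3)
        / (1.0 + s2 / down.k_m + s3 / km3)
    )
    return production - consumption


def chain_steady_state_reversible(chain: TwoEnzymeChain, s1: float) -> float:
    """Numerical steady-state S2 under the full reversible flux balance.

    Root of the monotone flux residual, found by Brent's method on a
    bracket grown by doubling; converges to the closed form of
    :func:`chain_steady_state_mm` as the reverse affinities K_M2', K_M3
    become large.
    """
    if not chain.is_reversible:
        raise ValueError(
            "chain has no reverse binding constants; use chain_steady_state_mm"
        )
    if s1 < 0:
        raise ValueError("s1 must be >= 0")
    if s1 == 0 and chain.downstream_product == 0:
        return 0.0
    resid = lambda s2: _flux_residual(chain, s1, s2)
    if resid(0.0) <= 0:
        return 0.0
    hi = max(chain.downstream.k_m, s1)
    for _ in range(200):
        if resid(hi) < 0:
            break
        hi *= 2.0
    else:
        raise NoSteadyStateError(
            f"flux residual does not change sign up to S2={hi:.3g}; "
            "upstream flux exceeds downstream capacity"
        )
    return float(brentq(resid, 0.0, hi, rtol=1e-14, maxiter=200))


def loglog_slopes(curve: SteadyStateCurve) -> np.ndarray:
    """Local log-log slopes d ln S2 / d ln S1 along a steady-state curve.

    Central differences in log space; one-sided at the endpoints.
    """
    if len(curve.s1_values) < 5:
        raise DataError("need at least 5 points for slope estimation")
    if np.any(curve.s2_values <= 0):
        raise DataError("curve must be strictly positive for log-log slopes")
    if not np.all(np.diff(curve.s2_values) >= 0):
        raise DataError("curve must be monotone non-decreasing")
    return np.gradient(np.log(curve.s2_values), np.log(curve.s1_values))


def apparent_hill_exponent(curve: SteadyStateCurve, at_low_s1: bool = True) -> float:
    """Apparent cooperativity of a steady-state S2-vs-S1 curve.

    With ``at_low_s1`` (default) returns the log-log slope at the lowest
    substrate value; for a Hill chain this limit equals m/n, the ratio of
    the upstream to downstream Hill coefficients.  Otherwise returns the
    maximum local slope over the curve (the conventional apparent Hill
    coefficient at the steepest point).
    """
    slopes = loglog_slopes(curve)
    return float(slopes[0]) if at_low_s1 else float(np.max(slopes))


def mutant_ratio_scan(
    model: Callable[[np.ndarray], np.ndarray],
    fold_drop: float,
    s1_grid: Sequence[float],
) -> pd.DataFrame:
    """Mutant/reference product ratio implied by a substrate fold-drop.

    For each assumed reference substrate level ``s1`` on the grid,
    computes ``ratio(s1) = S2(fold_drop*s1) / S2(s1)`` under the supplied
    steady-state model.  Under an MM-form model with C >= 0 the ratio is
    bounded below by ``fold_drop``; under a Hill-form model with exponent
    m the ratio approaches ``fold_drop**m`` in the low-substrate lag,
    which is how a 10-fold substrate drop can yield a >100-fold product
    drop.

    Returns a DataFrame with columns ``s1`` and ``ratio``.
    """
    if not 0 < fold_drop <= 1:
        raise ValueError("fold_drop must be in (0, 1]")
    s1 = np.asarray(s1_grid, dtype=float)
    if np.any(s1 <= 0):
        raise ValueError("s1 grid must be positive")
    reference = np.asarray(model(s1), dtype=float)
    mutant = np.asarray(model(fold_drop * s1), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(reference > 0, mutant / reference, np.nan)
    return pd.DataFrame({"s1": s1, "ratio": ratio})
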