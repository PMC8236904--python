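"""Model fitting for enzyme kinetics, in vitro and in vivo.

Rate laws fitted here:

* Michaelis-Menten  y = vmax*x/(k_m + x)
* 3-parameter Hill  y = amplitude*x**n/(k_half**n + x**n)
* 4-parameter log-logistic (dose-response, "4PL")
  y = bottom + (top - bottom)/(1 + (x/ic50)**slope)

MM is nested inside Hill (exponent fixed at 1), so the two are compared
with the extra sum-of-squares F-test: under the null (MM adequate) the
scaled SSR reduction follows an F distribution.  All fits are unweighted
bounded nonlinear least squares with multi-start, since the Hill surface
is multimodal in (k_half, exponent).

In vivo "activity curves" are assembled from steady-state metabolomics:
each biological replicate at each strain/condition/timepoint contributes
one (substrate level, product level) point, never averaged.  At steady
state the product pool is an invertible readout of the consuming flux, so
the shape of this scatter reflects the in vivo rate law of the enzyme
connecting the two pools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .chain import DataError
from .fractal import KineticTrace

__all__ = [
    "DoseResponsePoints",
    "FitResult",
    "ModelComparison",
    "InitialRate",
    "FitError",
    "EmptyResultError",
    "estimate_initial_rate",
    "fit_mm",
    "fit_hill",
    "fit_inhibition_4pl",
    "compare_models_ftest",
    "competitive_inhibition_rate",
    "build_invivo_curve",
]

logger = logging.getLogger(__name__)

_SSR_TOL = 1e-10  # relative convergence tolerance on the sum of squares


class FitError(RuntimeError):
    """Nonlinear fit failed to converge from every start point."""


class EmptyResultError(ValueError):
    """A query produced no usable data points."""


@dataclass(frozen=True)
class DoseResponsePoints:
    """Paired (x, y) observations: dose/substrate vs rate/product level."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, ...] = ()
    x_unit: str = "relative"
    y_unit: str = "relative"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if np.any(x < 0):
            raise ValueError("x (concentration) must be >= 0")
        if self.labels and len(self.labels) != len(x):
            raise ValueError("labels length must match number of points")

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"x": self.x, "y": self.y})
        if self.labels:
            frame["label"] = list(self.labels)
        return frame


@dataclass(frozen=True)
class InitialRate:
    """Initial rate from the linear phase of a kinetic trace."""

    rate: float
    stderr: float
    n_points: int
    intercept: float


@dataclass
class FitResult:
    """Outcome of a least-squares rate-law fit."""

    model_name: str
    params: dict[str, float]
    ssr: float
    n_points: int
    n_params: int
    converged: bool
    param_se: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    points: DoseResponsePoints | None = None

    @property
    def dof(self) -> int:
        return self.n_points - self.n_params

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.model_name == "MM":
            return p["vmax"] * x / (p["k_m"] + x)
        if self.model_name == "Hill3":
            n = p["exponent"]
            return p["amplitude"] * x**n / (p["k_half"] ** n + x**n)
        if self.model_name == "Sigmoid4PL":
            ratio = np.where(x > 0, (x / p["ic50"]) ** p["slope"], 0.0)
            return p["bottom"] + (p["top"] - p["bottom"]) / (1.0 + ratio)
        if self.model_name == "Linear":
            return p["intercept"] + p["slope"] * x
        raise ValueError(f"unknown model {self.model_name!r}")

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "params": dict(self.params),
            "param_se": dict(self.param_se),
            "ssr": self.ssr,
            "n_points": self.n_points,
            "n_params": self.n_params,
            "converged": self.converged,
            "flags": list(self.flags),
        }


@dataclass(frozen=True)
class ModelComparison:
    """Extra sum-of-squares F-test between nested least-squares fits."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    preferred: str
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "f_stat": self.f_stat,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p_value": self.p_value,
            "preferred": self.preferred,
            "alpha": self.alpha,
        }


def estimate_initial_rate(trace: KineticTrace, window: float = 20.0) -> InitialRate:
    """Initial rate from an OLS line through the first ``window`` time units.

    Consumption traces (decreasing signal) return a positive rate: the
    slope magnitude is reported.  Requires at least 3 points inside the
    window.
    """
    mask = trace.times <= trace.times[0] + window
    if mask.sum() < 3:
        raise DataError(
            f"only {int(mask.sum())} points within the {window} time-unit window; need >= 3"
        )
    res = stats.linregress(trace.times[mask], trace.values[mask])
    return InitialRate(
        rate=abs(float(res.slope)),
        stderr=float(res.stderr),
        n_points=int(mask.sum()),
        intercept=float(res.intercept),
    )


def _least_squares_multistart(residual, starts, bounds, n_points):
    """Run bounded least squares from several starts, keep the best SSR.

    Starts that stop on the iteration cap (flat, ill-conditioned designs)
    are kept as fallbacks and reported with ``success=False``; an error is
    raised only when every start fails outright.
    """
    best = fallback = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            sol = optimize.least_squares(
                residual, x0, bounds=bounds, xtol=1e-12, ftol=_SSR_TOL, max_nfev=2000
            )
        except Exception:  # singular step from a bad start: try the next
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
        elif not sol.success and (fallback is None or sol.cost < fallback.cost):
            fallback = sol
    if best is None and fallback is None:
        raise FitError(f"fit failed to converge from all {len(starts)} start points")
    if best is None or (fallback is not None and fallback.cost < best.cost):
        return fallback
    return best


def _param_se(sol, n_params: int, n_points: int) -> np.ndarray:
    """Asymptotic standard errors from the Jacobian at the optimum."""
    dof = n_points - n_params
    if dof <= 0:
        return np.full(n_params, np.nan)
    ssr = 2.0 * sol.cost
    try:
        jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
        return np.sqrt(np.clip(np.diag(jtj_inv) * ssr / dof, 0, None))
    except np.linalg.LinAlgError:
        return np.full(n_params, np.nan)


def _positive_x_range(x: np.ndarray) -> tuple[float, float]:
    pos = x[x > 0]
    if len(pos) == 0:
        return (1.0, 1.0)
    return float(pos.min()), float(pos.max())


def fit_mm(points: DoseResponsePoints) -> FitResult:
    """Fit the Michaelis-Menten law y = vmax*x/(k_m + x)."""
    x, y = points.x, points.y
    if len(points) < 3:
        raise DataError("MM fit needs at least 3 points")
    ymax = float(np.max(np.abs(y)))
    if ymax == 0:
        return FitResult(
            model_name="MM",
            params={"vmax": 0.0, "k_m": float(np.median(x[x > 0]) if np.any(x > 0) else 1.0)},
            ssr=0.0,
            n_points=len(points),
            n_params=2,
            converged=True,
            flags=["non_identifiable"],
            points=points,
        )
    lo, hi = _positive_x_range(x)
    residual = lambda p: p[0] * x / (p[1] + x) - y
    starts = [
        np.array([v0, k0])
        for v0 in (ymax, 2 * ymax)
        for k0 in np.geomspace(lo, hi, 2)
    ]
    sol = _least_squares_multistart(residual, starts, ([0.0, 1e-12], [np.inf, np.inf]), len(points))
    se = _param_se(sol, 2, len(points))
    return FitResult(
        model_name="MM",
        params={"vmax": float(sol.x[0]), "k_m": float(sol.x[1])},
        ssr=float(2.0 * sol.cost),
        n_points=len(points),
        n_params=2,
        converged=bool(sol.success),
        param_se={"vmax": float(se[0]), "k_m": float(se[1])},
        points=points,
    )


def fit_hill(
    points: DoseResponsePoints,
    fix_baseline_zero: bool = True,
    exponent_bounds: tuple[float, float] = (0.1, 10.0),
    extra_starts: Sequence[np.ndarray] = (),
) -> FitResult:
    """Fit the 3-parameter Hill law y = amplitude*x**n/(k_half**n + x**n).

    k_half is the half-saturation concentration; the denominator constant
    in the K + x**n parameterisation is recorded as ``k_m_apparent`` =
    k_half**n.  8 multi-starts (k_half log-spaced over the x range crossed
    with exponents {0.5, 1, 2, 4}) guard against the multimodal surface.
    """
    if not fix_baseline_zero:
        raise NotImplementedError("only the zero-baseline Hill form is supported")
    x, y = points.x, points.y
    if len(points) < 4:
        raise DataError("Hill fit needs at least 4 points")
    ymax = float(np.max(np.abs(y)))
    if ymax == 0:
        raise FitError("all-zero response: Hill parameters are not identifiable")
    lo, hi = _positive_x_range(x)

    def residual(p):
        amp, k_half, n = p
        xn = x**n
        return amp * xn / (k_half**n + xn) - y

    starts = [
        np.array([ymax * 1.05, k0, n0])
        for k0 in np.geomspace(lo, hi, 2)
        for n0 in (0.5, 1.0, 2.0, 4.0)
    ] + [np.asarray(s, dtype=float) for s in extra_starts]
    bounds = ([0.0, 1e-12, exponent_bounds[0]], [np.inf, np.inf, exponent_bounds[1]])
    sol = _least_squares_multistart(residual, starts, bounds, len(points))
    se = _param_se(sol, 3, len(points))
    amp, k_half, n = (float(v) for v in sol.x)
    return FitResult(
        model_name="Hill3",
        params={
            "amplitude": amp,
            "k_half": k_half,
            "exponent": n,
            "k_m_apparent": k_half**n,
        },
        ssr=float(2.0 * sol.cost),
        n_points=len(points),
        n_params=3,
        converged=bool(sol.success),
        param_se={"amplitude": float(se[0]), "k_half": float(se[1]), "exponent": float(se[2])},
        points=points,
    )


def fit_inhibition_4pl(points: DoseResponsePoints) -> FitResult:
    """Fit a 4-parameter log-logistic dose-response to rate-vs-inhibitor data.

    y = bottom + (top - bottom)/(1 + (x/ic50)**slope).  The fitted
    midpoint ic50 is reported as the apparent inhibition constant
    (``apparent_ki``): the operational K_I read directly off the sigmoid,
    with no competition-model correction.  Flat (uninhibited) data leave
    the slope non-identifiable and are flagged.
    """
    x, y = points.x, points.y
    if len(points) < 5:
        raise DataError("4PL fit needs at least 5 inhibitor concentrations")
    lo, hi = _positive_x_range(x)

    def residual(p):
        top, bottom, ic50, slope = p
        ratio = np.where(x > 0, (x / ic50) ** slope, 0.0)
        return bottom + (top - bottom) / (1.0 + ratio) - y

    y_top, y_bot = float(np.max(y)), float(np.min(y))
    starts = [
        np.array([y_top, y_bot, ic0, s0])
        for ic0 in (np.sqrt(lo * hi), np.median(x[x > 0]) if np.any(x > 0) else 1.0)
        for s0 in (0.5, 1.0, 2.0)
    ]
    bounds = ([0.0, 0.0, 1e-12, 0.1], [np.inf, np.inf, np.inf, 10.0])
    sol = _least_squares_multistart(residual, starts, bounds, len(points))
    se = _param_se(sol, 4, len(points))
    top, bottom, ic50, slope = (float(v) for v in sol.x)
    flags = []
    span = abs(top - bottom)
    if span <= 1e-3 * max(abs(top), abs(bottom), 1e-300):
        flags.append("slope_non_identifiable")
    return FitResult(
        model_name="Sigmoid4PL",
        params={
            "top": top,
            "bottom": bottom,
            "ic50": ic50,
            "slope": slope,
            "apparent_ki": ic50,
        },
        ssr=float(2.0 * sol.cost),
        n_points=len(points),
        n_params=4,
        converged=bool(sol.success),
        param_se={
            "top": float(se[0]),
            "bottom": float(se[1]),
            "ic50": float(se[2]),
            "slope": float(se[3]),
        },
        flags=flags,
        points=points,
    )


def compare_models_ftest(
    nested: FitResult, full: FitResult, alpha: float = 0.05
) -> ModelComparison:
    """Extra sum-of-squares F-test of a nested against a fuller model.

    F = ((SSR_n - SSR_f)/(p_f - p_n)) / (SSR_f/(N - p_f)); the fuller
    model is preferred when p < alpha.  Both fits must be on the same
    points.  If the full model's SSR exceeds the nested one's (a failed
    optimisation, impossible at the true optimum), the full model is
    refitted starting from the nested solution.
    """
    if full.n_params <= nested.n_params:
        raise ValueError("the full model must have more parameters than the nested one")
    if (
        nested.points is None
        or full.points is None
        or not np.array_equal(nested.points.x, full.points.x)
        or not np.array_equal(nested.points.y, full.points.y)
    ):
        raise ValueError("both fits must be on the same data points")

    ssr_n, ssr_f = nested.ssr, full.ssr
    if ssr_f > ssr_n * (1 + 1e-12) and nested.model_name == "MM" and full.model_name == "Hill3":
        refit = fit_hill(
            full.points,
            extra_starts=[
                np.array([nested.params["vmax"], nested.params["k_m"], 1.0])
            ],
        )
        if refit.ssr < ssr_f:
            full = refit
            ssr_f = refit.ssr
    ssr_f = min(ssr_f, ssr_n)  # nesting guarantees the optimum obeys this

    df_num = full.n_params - nested.n_params
    df_den = full.n_points - full.n_params
    if df_den <= 0:
        raise ValueError("full model leaves no residual degrees of freedom")
    if ssr_f == 0.0:
        f_stat, p_value = np.inf, 0.0
    else:
        f_stat = ((ssr_n - ssr_f) / df_num) / (ssr_f / df_den)
        p_value = float(stats.f.sf(f_stat, df_num, df_den))
    preferred = full.model_name if p_value < alpha else nested.model_name
    return ModelComparison(
        f_stat=float(f_stat),
        df_num=df_num,
        df_den=df_den,
        p_value=p_value,
        preferred=preferred,
        alpha=alpha,
    )


def competitive_inhibition_rate(
    s: float, i: float, vmax: float, km: float, ki: float
):
    """Classical competitive inhibition: v = vmax*s/(km*(1 + i/ki) + s).

    Used for plausibility arithmetic: given measured K_M, apparent K_I and
    estimated intracellular substrate/inhibitor pools, how much inhibition
    could the inhibitor exert in vivo?  With i = 0 this is exactly
    :func:`invivokin.chain.mm_rate`.
    """
    if ki <= 0 or km <= 0 or vmax <= 0:
        raise ValueError("vmax, km and ki must be > 0")
    s = np.asarray(s, dtype=float)
    i = np.asarray(i, dtype=float)
    if np.any(s < 0) or np.any(i < 0):
        raise ValueError("concentrations must be >= 0")
    out = vmax * s / (km * (1.0 + i / ki) + s)
    return out if out.ndim else float(out)


_KEY_COLUMNS = ["strain", "condition", "supplement_mM", "timepoint_h", "replicate"]


def build_invivo_curve(
    table,
    substrate_name: str,
    product_name: str,
    dtmp_supplemented: bool | None = None,
) -> DoseResponsePoints:
    """Assemble an in vivo activity curve from a metabolomics table.

    Each (strain, condition, supplement dose, timepoint, replicate) key at
    which both metabolites were detected contributes one point:
    x = relative substrate level, y = relative product level.  Replicates
    are kept individually, never averaged.  Keys where either metabolite
    is censored (below the detection limit) are skipped with a logged
    warning.  ``dtmp_supplemented`` partitions points by whether the
    growth condition contained external dTMP (None keeps all points);
    thymidine-supplemented conditions count as unsupplemented, since
    externally supplied dTMP — not thymidine — is what switches the
    apparent kinetics.
    """
    df = table.df if hasattr(table, "df") else table
    sub = df[df["metabolite"].isin([substrate_name, product_name])]
    if dtmp_supplemented is not None:
        is_dtmp = sub["condition"].str.contains("dTMP", case=False) & (
            sub["supplement_mM"] > 0
        )
        sub = sub[is_dtmp] if dtmp_supplemented else sub[~is_dtmp]
    if sub.empty:
        raise EmptyResultError(
            f"no rows for metabolites {substrate_name!r}/{product_name!r} "
            "under the requested condition filter"
        )

    xs, ys, labels = [], [], []
    n_censored = n_incomplete = 0
    for key, group in sub.groupby(_KEY_COLUMNS, sort=True):
        by_met = group.set_index("metabolite")
        if substrate_name not in by_met.index or product_name not in by_met.index:
            n_incomplete += 1
            continue
        s_row = by_met.loc[substrate_name]
        p_row = by_met.loc[product_name]
        if bool(s_row["is_censored"]) or bool(p_row["is_censored"]):
            n_censored += 1
            continue
        xs.append(float(s_row["relative_abundance"]))
        ys.append(float(p_row["relative_abundance"]))
        labels.append("/".join(str(k) for k in key))
    if n_incomplete:
        logger.warning(
            "%d keys skipped: one of %s/%s missing", n_incomplete, substrate_name, product_name
        )
    if n_censored:
        logger.warning(
            "%d keys excluded: %s or %s below the detection limit",
            n_censored,
            substrate_name,
            product_name,
        )
    if not xs:
        raise EmptyResultError("no keys with both metabolites detected")
    return DoseResponsePoints(
        x=np.array(xs), y=np.array(ys), labels=tuple(labels), x_unit="relative", y_unit="relative"
    )
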