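"""Maintenance-energy kinetics of retentostat cultures.

A retentostat is a chemostat in which the effluent is removed through a
filter so that biomass is fully retained.  At a fixed dilution rate ``D``
on a growth-limiting energy substrate, biomass accumulates and the
biomass-specific substrate supply falls until it only covers maintenance,
so the specific growth rate asymptotically approaches zero.

Under "ideal" conditions (growth-rate-independent maintenance-energy
requirement, no lysis, full viability) the biomass balance is

    dCx/dt = Ysx_max * (D * (Cs_in - Cs) - ms_g * Cx)

with ``Cx`` the biomass concentration (g L-1), ``Cs_in`` and ``Cs`` the
feed and residual substrate concentrations (g L-1), ``ms_g`` the
maintenance coefficient in g glucose (g biomass)-1 h-1 and ``Ysx_max``
the maximum biomass yield on substrate (g g-1).  The solution is

    Cx(t) = Cx_inf + (Cx0 - Cx_inf) * exp(-k * t)

with decay constant ``k = ms_g * Ysx_max`` and the maintenance-only
ceiling ``Cx_inf = D * (Cs_in - Cs) / ms_g`` at which the whole substrate
supply is spent on maintenance.

Observed total-biomass trajectories are fitted with the same shape
``A*exp(B*t) + C`` by derivative-free least squares (Nelder-Mead), the
accumulation rate ``dCx/dt = A*B*exp(B*t)`` is taken analytically from the
fit, and the specific growth rate is reconstructed by attributing all
biomass formation to the viable cells:

    mu(t) = (dCx/dt) / (viability(t) * Cx(t))

The glucose consumption flux is partitioned between maintenance
(``ms_g * Cx_viable``) and growth (``mu * Cx_viable / Ysx_max``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "GLUCOSE_MW_G_PER_MMOL",
    "RetentostatParams",
    "BiomassTimeSeries",
    "FitResult",
    "GrowthRateProfile",
    "GlucosePartition",
    "ParameterError",
    "InsufficientDataError",
    "predict_biomass",
    "chemostat_steady_state_biomass",
    "fit_biomass_curve",
    "specific_growth_rate",
    "doubling_time",
    "glucose_partition",
    "residual_glucose_monod",
]

#: molar mass of anhydrous D-glucose, g per mmol
GLUCOSE_MW_G_PER_MMOL = 0.18016


class ParameterError(ValueError):
    """Invalid kinetic parameter(s)."""


class InsufficientDataError(ValueError):
    """Too few data points for the requested operation."""


@dataclass(frozen=True)
class RetentostatParams:
    """Kinetic constants of a glucose-limited retentostat.

    Parameters
    ----------
    D : dilution rate (h-1).
    Cs_in : feed glucose concentration (g L-1).
    Cs : residual glucose concentration (g L-1); three orders of magnitude
        below the feed in practice, default 0.
    ms_mmol : maintenance coefficient (mmol glucose g-1 h-1), default 0.50.
    Ysx_max : maximum biomass yield on glucose (g g-1), default 0.097.
    Cx0 : biomass concentration at the retentostat start (g L-1); if None,
        the steady-state biomass of a chemostat run at ``mu = D`` is used.
    mw_glucose : glucose molar mass (g mmol-1).
    """

    D: float
    Cs_in: float
    Cs: float = 0.0
    ms_mmol: float = 0.50
    Ysx_max: float = 0.097
    Cx0: float | None = None
    mw_glucose: float = GLUCOSE_MW_G_PER_MMOL

    def __post_init__(self) -> None:
        positives = {
            "D": self.D,
            "Cs_in": self.Cs_in,
            "ms_mmol": self.ms_mmol,
            "Ysx_max": self.Ysx_max,
            "mw_glucose": self.mw_glucose,
        }
        for name, value in positives.items():
            if not np.isfinite(value) or value <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {value!r}")
        if not np.isfinite(self.Cs) or self.Cs < 0:
            raise ParameterError(f"Cs must be finite and >= 0, got {self.Cs!r}")
        if self.Cs >= self.Cs_in:
            raise ParameterError("residual glucose Cs must be below the feed Cs_in")
        if self.Cx0 is not None and (not np.isfinite(self.Cx0) or self.Cx0 <= 0):
            raise ParameterError(f"Cx0 must be finite and > 0, got {self.Cx0!r}")

    @property
    def ms_g(self) -> float:
        """Maintenance coefficient in g glucose (g biomass)-1 h-1."""
        return self.ms_mmol * self.mw_glucose

    @property
    def cx_inf(self) -> float:
        """Maintenance-only biomass ceiling D*(Cs_in - Cs)/ms_g (g L-1)."""
        return self.D * (self.Cs_in - self.Cs) / self.ms_g

    @property
    def cx0_effective(self) -> float:
        """Initial biomass: explicit Cx0 or the chemostat steady state."""
        if self.Cx0 is not None:
            return self.Cx0
        return chemostat_steady_state_biomass(self)


@dataclass(frozen=True)
class BiomassTimeSeries:
    """Measured total-biomass trajectory with viability.

    ``Cx_total`` includes both viable and non-viable cells; ``viability``
    is the viable fraction in [0, 1] at each sampling time.
    """

    t: np.ndarray
    Cx_total: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        cx = np.asarray(self.Cx_total, dtype=float)
        v = np.asarray(self.viability, dtype=float)
        if not (t.shape == cx.shape == v.shape) or t.ndim != 1:
            raise ValueError("t, Cx_total and viability must be 1-d and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if not np.all(np.isfinite(cx)) or np.any(cx <= 0):
            raise ValueError("Cx_total must be finite and > 0")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("viability must lie in [0, 1]")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "Cx_total", cx)
        object.__setattr__(self, "viability", v)

    def __len__(self) -> int:
        return self.t.size

    def viability_at(self, t: np.ndarray) -> np.ndarray:
        """Viable fraction, linearly interpolated between sampling points."""
        return np.interp(np.asarray(t, dtype=float), self.t, self.viability)


@dataclass(frozen=True)
class FitResult:
    """Coefficients of the A*exp(B*t) + C least-squares fit."""

    A: float
    B: float
    C: float
    sse: float
    converged: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.A * np.exp(self.B * t) + self.C

    def derivative(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.A * self.B * np.exp(self.B * t)


@dataclass(frozen=True)
class GrowthRateProfile:
    """Specific growth rate reconstructed from a fitted trajectory.

    ``clipped`` flags times at which the fitted derivative was negative and
    mu was reported as 0 (a negative mu would violate the no-lysis
    assumption under which the reconstruction is valid).
    """

    t: np.ndarray
    mu: np.ndarray
    dCx_dt: np.ndarray
    Cx_fit: np.ndarray
    Cx_viable: np.ndarray
    clipped: np.ndarray


@dataclass(frozen=True)
class GlucosePartition:
    """Split of the glucose consumption flux between maintenance and growth.

    Fluxes are in g glucose L-1 h-1; the fractions sum to 1 except where
    both fluxes are zero (``degenerate`` flags those entries, fractions NaN).
    """

    maintenance_flux: np.ndarray
    growth_flux: np.ndarray
    frac_maintenance: np.ndarray
    frac_growth: np.ndarray
    degenerate: np.ndarray


def predict_biomass(params: RetentostatParams, t) -> np.ndarray | float:
    """Biomass concentration (g L-1) of an ideal retentostat at time ``t`` (h).

    Closed-form solution of the maintenance-limited biomass balance; at
    ``t = 0`` it equals ``Cx0`` and for large ``t`` it approaches the
    maintenance-only steady state ``D*(Cs_in - Cs)/ms_g``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    k = params.ms_g * params.Ysx_max
    cx_inf = params.cx_inf
    cx0 = params.cx0_effective
    out = cx_inf + (cx0 - cx_inf) * np.exp(-k * t_arr)
    return float(out) if np.isscalar(t) else out


def chemostat_steady_state_biomass(params: RetentostatParams) -> float:
    """Steady-state biomass of a chemostat run at ``mu = D`` (g L-1).

    Uses the maintenance-corrected (Pirt) observed yield
    ``1/Y_obs = 1/Ysx_max + ms_g/D`` applied to the consumed substrate
    ``Cs_in - Cs``.
    """
    if params.D <= 0:
        raise ZeroDivisionError("chemostat steady state requires D > 0")
    y_obs = 1.0 / (1.0 / params.Ysx_max + params.ms_g / params.D)
    return (params.Cs_in - params.Cs) * y_obs


def fit_biomass_curve(
    series: BiomassTimeSeries,
    init: Sequence[float] | None = None,
) -> FitResult:
    """Least-squares fit of ``Cx = A*exp(B*t) + C`` to a total-biomass series.

    Nelder-Mead simplex minimization of the sum of squared residuals.  The
    default initialization sets the asymptote slightly above the largest
    observation (``C0 = 1.05*max(Cx)``, ``A0 = Cx(0) - C0``,
    ``B0 = -0.01 h-1``), appropriate for a retentostat-shaped saturating
    trajectory.  On non-convergence the best-so-far coefficients are
    returned with ``converged=False`` (no exception).
    """
    if len(series) < 4:
        raise InsufficientDataError(
            f"need >= 4 time points to fit A*exp(B*t)+C, got {len(series)}"
        )
    t, y = series.t, series.Cx_total
    mean_y = float(np.mean(y))
    if np.allclose(y, mean_y, rtol=0, atol=1e-12 * abs(mean_y)):
        # constant data: A*exp(B*t)+C is unidentifiable along A+C = const;
        # resolve the degeneracy to the flat solution A = 0, C = mean
        sse0 = float(np.sum((y - mean_y) ** 2))
        return FitResult(A=0.0, B=-0.01, C=mean_y, sse=sse0, converged=True)
    if init is None:
        c0 = 1.05 * float(np.max(y))
        init = (float(y[0]) - c0, -0.01, c0)

    def sse(theta: np.ndarray) -> float:
        a, b, c = theta
        with np.errstate(over="ignore"):
            resid = y - (a * np.exp(b * t) + c)
        resid = np.where(np.isfinite(resid), resid, 1e150)
        return float(resid @ resid)

    res = minimize(
        sse,
        np.asarray(init, dtype=float),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxfev": 10_000, "maxiter": 10_000},
    )
    a, b, c = (float(v) for v in res.x)
    return FitResult(A=a, B=b, C=c, sse=float(res.fun), converged=bool(res.success))


def specific_growth_rate(
    fit: FitResult,
    series: BiomassTimeSeries,
    t=None,
) -> GrowthRateProfile:
    """Reconstruct mu(t) = (dCx/dt) / (viability * Cx) from a fitted curve.

    Growth is attributed to viable biomass only, assuming no lysis (dead
    cells remain in the measured total).  The derivative is analytic from
    the fit; viability is linearly interpolated between sampling points.
    Negative derivatives are clipped to mu = 0 and flagged.
    """
    t_req = series.t if t is None else np.asarray(t, dtype=float)
    v = series.viability_at(t_req)
    zero = np.nonzero(v <= 0)[0]
    if zero.size:
        raise ZeroDivisionError(
            f"viability is 0 at t = {t_req[zero[0]]:g} h; mu is undefined there"
        )
    cx_fit = fit.predict(t_req)
    dcx = fit.derivative(t_req)
    mu_raw = dcx / (v * cx_fit)
    clipped = mu_raw < 0
    mu = np.where(clipped, 0.0, mu_raw)
    return GrowthRateProfile(
        t=t_req,
        mu=mu,
        dCx_dt=dcx,
        Cx_fit=cx_fit,
        Cx_viable=v * cx_fit,
        clipped=clipped,
    )


def doubling_time(mu) -> np.ndarray | float:
    """Population doubling time ln(2)/mu in hours; +inf for mu <= 0."""
    mu_arr = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        td = np.where(mu_arr > 0, math.log(2) / mu_arr, np.inf)
    return float(td) if np.isscalar(mu) else td


def glucose_partition(
    params: RetentostatParams,
    Cx_viable,
    mu,
) -> GlucosePartition:
    """Partition glucose consumption between maintenance and growth.

    maintenance flux = ms_g * Cx_viable, growth flux = mu * Cx_viable / Ysx_max
    (both g glucose L-1 h-1); fractions are each flux over their sum.
    Entries where both fluxes are zero are flagged degenerate with NaN
    fractions.
    """
    cxv = np.atleast_1d(np.asarray(Cx_viable, dtype=float))
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    cxv, mu_arr = np.broadcast_arrays(cxv, mu_arr)
    if np.any(cxv < 0) or np.any(mu_arr < 0):
        raise ValueError("Cx_viable and mu must be >= 0")
    maint = params.ms_g * cxv
    growth = mu_arr * cxv / params.Ysx_max
    total = maint + growth
    degenerate = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_m = np.where(degenerate, np.nan, maint / total)
        frac_g = np.where(degenerate, np.nan, growth / total)
    return GlucosePartition(
        maintenance_flux=maint,
        growth_flux=growth,
        frac_maintenance=frac_m,
        frac_growth=frac_g,
        degenerate=degenerate,
    )


def residual_glucose_monod(
    mu,
    qs_max: float = 15.0,
    Ks: float = 0.8,
    ms_mmol: float = 0.50,
    Ysx_max: float = 0.097,
    mw_glucose: float = GLUCOSE_MW_G_PER_MMOL,
) -> np.ndarray | float:
    """Residual glucose concentration (mM) implied by Monod uptake kinetics.

    The specific glucose consumption rate follows the Pirt relation
    ``qs = mu / (Ysx_max * mw) + ms_mmol`` (mmol g-1 h-1); inverting the
    Monod curve ``qs = qs_max * Cs / (Ks + Cs)`` gives
    ``Cs = Ks * qs / (qs_max - qs)``.  Monotone increasing in mu, with a
    positive floor ``Ks*ms/(qs_max - ms)`` as mu -> 0 because maintenance
    consumption never stops.
    """
    mu_arr = np.asarray(mu, dtype=float)
    if np.any(mu_arr < 0):
        raise ValueError("mu must be >= 0")
    qs = mu_arr / (Ysx_max * mw_glucose) + ms_mmol
    if np.any(qs >= qs_max):
        raise ValueError(
            "implied glucose consumption reaches qs_max; Monod curve saturates"
        )
    cs = Ks * qs / (qs_max - qs)
    return float(cs) if np.isscalar(mu) else cs
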