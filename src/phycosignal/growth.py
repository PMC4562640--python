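"""Growth-curve fitting, Monod resource-response models and R* estimation.

From daily chlorophyll-a fluorescence readings of plate wells we estimate a
per-well exponential growth rate r (fit of ln RFU on day, trimming
density-dependent plateau points off the end of the series until the R² of
the exponential fit is maximised).  The (resource level, growth rate)
pairs for a species are then fit by nonlinear least squares to either

* the Monod model      μ(R) = μ_max·R / (R + μ_max/α) − D, or
* a light-optimum model in which growth is maximised at R_opt and declines
  above it (relevant for photoinhibition at high irradiance),

with D the dilution rate (0.05 day⁻¹ by default, standing in for the 10%
media exchanges of a semi-continuous culture).  AIC chooses between the two
forms, and the fitted function is solved for the zero-net-growth resource
level R* — the concentration at which net growth is exactly zero, the
classic predictor of competitive ability for that resource.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "FluorescenceSeries",
    "GrowthRateEstimate",
    "ResourceResponse",
    "MonodParams",
    "RStar",
    "GrowthFitError",
    "estimate_growth_rate",
    "monod_mu",
    "light_optimum_mu",
    "fit_monod",
    "fit_light_optimum",
    "select_growth_model",
    "solve_rstar",
]


class GrowthFitError(RuntimeError):
    """Nonlinear growth-response fit failed or was fed degenerate data."""


@dataclass(frozen=True)
class FluorescenceSeries:
    """Daily RFU readings for one well (one species × treatment × replicate)."""

    species_id: str
    treatment_value: float
    replicate: int
    readings: tuple  # of (day, rfu) pairs, days strictly increasing
    resource_kind: str = "nitrate"

    def __post_init__(self):
        days = [d for d, _ in self.readings]
        rfus = [f for _, f in self.readings]
        if len(self.readings) < 2:
            raise ValueError("need at least 2 readings")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        if not all(np.isfinite(rfus)):
            raise ValueError("non-finite RFU value")


@dataclass(frozen=True)
class GrowthRateEstimate:
    r: float
    f0: float
    r_squared: float
    n_points_used: int
    excluded: bool


@dataclass(frozen=True)
class ResourceResponse:
    species_id: str
    points: tuple  # of (resource_level, growth_rate)
    resource_kind: str = "nitrate"


@dataclass(frozen=True)
class MonodParams:
    form: str  # "monod" | "optimum"
    alpha_slope: float
    mu_max: float
    dilution: float
    sse: float
    aic: float
    r_opt: float | None = None
    points: tuple = ()

    def mu(self, resource: float | np.ndarray) -> float | np.ndarray:
        if self.form == "monod":
            return monod_mu(resource, self.alpha_slope, self.mu_max, self.dilution)
        return light_optimum_mu(
            resource, self.alpha_slope, self.mu_max, self.r_opt, self.dilution
        )


@dataclass(frozen=True)
class RStar:
    species_id: str
    resource_kind: str
    value: float
    attainable: bool


# ---------------------------------------------------------------------------
# exponential growth rate with suffix trimming


def estimate_growth_rate(
    series: FluorescenceSeries, min_points: int = 4
) -> GrowthRateEstimate:
    """Exponential growth rate from a fluorescence time series.

    Fits ln(RFU) on day by OLS, eliminating readings from the end of the
    series one at a time until the R² of the fit stops improving (never
    below ``min_points`` readings).  This removes the density-dependent
    plateau at the end of a well's trajectory while keeping the full
    exponential head; stopping at the first non-improvement (rather than
    scanning all truncations for a global R² maximum) avoids rewarding
    short windows that happen to align with noise in slow-growing wells.
    A final fit with r ≤ 0 is flagged ``excluded`` (zero/negative-growth
    series do not enter the resource-response fit).
    """
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    days = np.array([d for d, _ in series.readings], dtype=float)
    rfu = np.array([f for _, f in series.readings], dtype=float)
    if np.any(rfu <= 0):
        raise ValueError("RFU values must be positive (log undefined)")
    if len(days) < min_points:
        raise ValueError(f"need at least {min_points} readings, got {len(days)}")
    y = np.log(rfu)

    def ols(n):
        x_, y_ = days[:n], y[:n]
        slope, intercept = np.polyfit(x_, y_, 1)
        resid = y_ - (slope * x_ + intercept)
        ss_tot = float(np.sum((y_ - y_.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
        return min(max(r2, 0.0), 1.0), slope, intercept

    n = len(days)
    r2, slope, intercept = ols(n)
    while n > min_points:
        r2_next, slope_next, icpt_next = ols(n - 1)
        if r2_next <= r2 + 1e-12:  # no strict improvement: keep longer series
            break
        n, r2, slope, intercept = n - 1, r2_next, slope_next, icpt_next
    return GrowthRateEstimate(
        r=float(slope),
        f0=float(math.exp(intercept)),
        r_squared=float(r2),
        n_points_used=int(n),
        excluded=bool(slope <= 0),
    )


# ---------------------------------------------------------------------------
# resource-response models


def monod_mu(resource, alpha, mu_max, dilution):
    """Net growth rate under the Monod model: μ_max·R/(R + μ_max/α) − D."""
    resource = np.asarray(resource, dtype=float)
    half_sat = mu_max / alpha
    return mu_max * resource / (resource + half_sat) - dilution


def light_optimum_mu(resource, alpha, mu_max, r_opt, dilution):
    """Net growth under the light-optimum model.

    Hump-shaped in R: rises with initial slope α, peaks at exactly
    μ_max − D when R = R_opt, and declines beyond (photoinhibition).
    """
    r = np.asarray(resource, dtype=float)
    a = mu_max / (alpha * r_opt**2)
    b = 1.0 - 2.0 * mu_max / (alpha * r_opt)
    c = mu_max / alpha
    denom = a * r**2 + b * r + c
    return mu_max * r / denom - dilution


def _aic_gaussian(sse: float, n: int, k_model: int) -> float:
    # k_model structural parameters + 1 for the error variance
    sse = max(sse, 1e-300)
    return n * math.log(sse / n) + 2.0 * (k_model + 1)


def _nls(resp: ResourceResponse, dilution: float, form: str) -> MonodParams:
    pts = sorted(resp.points)
    levels = np.array([p[0] for p in pts], dtype=float)
    rates = np.array([p[1] for p in pts], dtype=float)
    if len(pts) < 4:
        raise GrowthFitError("need at least 4 (resource, rate) points")
    if np.any(levels < 0) or len(set(levels.tolist())) < 3:
        raise GrowthFitError("resource levels must be non-negative and varied")
    if np.allclose(rates, rates[0]):
        raise GrowthFitError("all growth rates identical: nothing to fit")
    if np.all(rates <= -dilution):
        raise GrowthFitError("no growth signal: all rates at or below -D")

    mu0 = max(rates.max() + dilution, 1e-3)
    nz = levels > 0
    if nz.sum() >= 2:
        lv, rt = levels[nz][:2], rates[nz][:2]
        if lv[1] > lv[0]:
            alpha0 = (rt[1] - rt[0]) / (lv[1] - lv[0])
        else:
            alpha0 = mu0 / max(lv[0], 1e-6)
    else:
        alpha0 = 1.0
    if not np.isfinite(alpha0) or alpha0 <= 0:
        alpha0 = mu0 / max(levels[nz].min() if nz.any() else 1.0, 1e-6)

    starts = []
    for fa in (0.5, 1.0, 2.0):
        for fm in (0.5, 1.0, 2.0):
            starts.append((alpha0 * fa, mu0 * fm))

    if form == "monod":
        def resid(p):
            return monod_mu(levels, p[0], p[1], dilution) - rates
        lb, ub = [1e-9, 1e-9], [np.inf, np.inf]
        packs = [(a, m) for a, m in starts]
        k_model = 2
    else:
        ropt0 = float(levels[np.argmax(rates)]) or float(levels.max()) or 1.0
        def resid(p):
            return light_optimum_mu(levels, p[0], p[1], p[2], dilution) - rates
        # an optimum far beyond the observed range is unidentifiable; cap it
        ropt_max = 100.0 * float(levels.max() or 1.0)
        lb, ub = [1e-9, 1e-9, 1e-9], [np.inf, np.inf, ropt_max]
        packs = [(a, m, min(ropt0, ropt_max)) for (a, m) in starts]
        k_model = 3

    # cheap screen over every start, then a tight polish of the best one
    best = None
    for p0 in packs:
        try:
            sol = optimize.least_squares(
                resid, np.array(p0), bounds=(lb, ub), method="trf", max_nfev=60,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        sse = float(2.0 * sol.cost)
        if best is None or sse < best[0]:
            best = (sse, sol.x)
    if best is None:
        raise GrowthFitError(f"{form} fit failed to converge from any start")
    sol = optimize.least_squares(
        resid, best[1], bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12,
        gtol=1e-12, max_nfev=400,
    )
    sse, x = float(2.0 * sol.cost), sol.x
    if sse > best[0]:
        sse, x = best
    aic = _aic_gaussian(sse, len(pts), k_model)
    return MonodParams(
        form=form,
        alpha_slope=float(x[0]),
        mu_max=float(x[1]),
        r_opt=float(x[2]) if form == "optimum" else None,
        dilution=float(dilution),
        sse=sse,
        aic=aic,
        points=tuple(pts),
    )


def fit_monod(resp: ResourceResponse, dilution: float = 0.05) -> MonodParams:
    """Nonlinear least-squares Monod fit with multi-start initialisation."""
    return _nls(resp, dilution, "monod")


def fit_light_optimum(resp: ResourceResponse, dilution: float = 0.05) -> MonodParams:
    """Nonlinear least-squares fit of the hump-shaped light-optimum model."""
    return _nls(resp, dilution, "optimum")


def select_growth_model(m: MonodParams, o: MonodParams) -> MonodParams:
    """Pick the resource-response form with the lower AIC; ties go to Monod."""
    if m.points != o.points:
        raise ValueError("fits were made on different point sets")
    if m.form != "monod" or o.form != "optimum":
        raise ValueError("expected a monod fit and an optimum fit")
    return o if o.aic < m.aic else m


def solve_rstar(p: MonodParams, species_id: str = "", resource_kind: str = "") -> RStar:
    """Resource level at which net growth is zero.

    Monod form has the closed solution R* = D·μ_max / (α·(μ_max − D));
    the optimum form is solved by bracketed root-finding on (0, R_opt].
    When μ_max ≤ D the population cannot break even at any resource level
    and R* is flagged unattainable.
    """
    if p.mu_max <= p.dilution:
        return RStar(species_id, resource_kind, value=float("nan"), attainable=False)
    if p.dilution == 0:
        return RStar(species_id, resource_kind, value=0.0, attainable=True)
    if p.form == "monod":
        value = p.dilution * p.mu_max / (p.alpha_slope * (p.mu_max - p.dilution))
    else:
        f = lambda r: light_optimum_mu(r, p.alpha_slope, p.mu_max, p.r_opt, p.dilution)
        lo = p.r_opt * 1e-12
        while f(lo) >= 0 and lo > 1e-300:
            lo *= 1e-3
        value = float(optimize.brentq(f, lo, p.r_opt, xtol=1e-12, rtol=1e-14))
    return RStar(species_id, resource_kind, value=float(value), attainable=True)
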