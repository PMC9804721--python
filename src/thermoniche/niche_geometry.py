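"""Geometry of the consumer's realized thermal niche in the (T, R) plane.

The zero-net-growth isocline (ZNGI) of the consumer is the set of
temperature / resource-density combinations where per-unit growth is exactly
zero.  Read vertically it gives R*(T), the lowest resource density
permitting growth at temperature T (Tilman's R*); read horizontally it gives
the thermal limits Tmin(R) and Tmax(R) at fixed resource density.  As R
declines toward the minimum of R*(T) the limits converge and the growth TPC
collapses to a point, while the optimum temperature Topt(R) slides to cooler
values because respiration rises monotonically with T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .errors import NoNicheError
from .thermal_rates import (
    ConsumerParams,
    ResourceTraits,
    carrying_capacity,
    consumer_percap_growth,
    max_ingestion,
    respiration,
)

__all__ = [
    "rstar",
    "thermal_limits",
    "optimal_temperature",
    "niche_envelope",
    "realized_tpc",
    "NicheEnvelope",
]

#: Default coarse-scan window (degC) for bracketing roots in T.
SCAN_RANGE = (-20.0, 60.0)
SCAN_STEP = 0.05
ROOT_XTOL = 1e-10


def _net_gain(T, cp: ConsumerParams):
    """Saturated net gain ``(1 - delta) * Imax(T) - m(T)`` (R -> inf limit)."""
    return (1.0 - cp.delta) * max_ingestion(T, cp) - respiration(T, cp)


def rstar(T, cp: ConsumerParams):
    """Minimum resource density for zero net growth, ``R*(T)``.

    Closed form ``R_0 * m(T) / ((1 - delta) * Imax(T) - m(T))`` where the
    denominator is positive; NaN (infeasible) where no resource density
    permits growth at T.  Vectorised over T.
    """
    T = np.asarray(T, dtype=float)
    m = respiration(T, cp)
    den = (1.0 - cp.delta) * max_ingestion(T, cp) - m
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, cp.R_0 * m / np.where(den > 0, den, 1.0), np.nan)
    return out if out.ndim else float(out)


def _growth_in_T(R, cp):
    if np.isinf(R):
        return lambda T: _net_gain(T, cp)
    return lambda T: consumer_percap_growth(R, T, cp)


def thermal_limits(R, cp: ConsumerParams,
                   scan=SCAN_RANGE, step: float = SCAN_STEP) -> tuple[float, float]:
    """Thermal limits (Tmin, Tmax) of the growth TPC at resource density R.

    The two roots of ``consumer_percap_growth(R, .)`` bracketing the region
    of positive growth, refined by Brent's method.  ``R = inf`` gives the
    fundamental (resource-saturated) limits from the analytic R -> inf
    limit.  Raises :class:`NoNicheError` when R lies below the minimum of
    R*(T), i.e. growth is nowhere positive.
    """
    if not (R > 0):
        raise ValueError("R must be positive (np.inf allowed for saturation)")
    g = _growth_in_T(R, cp)
    T = np.arange(scan[0], scan[1] + step / 2, step)
    vals = g(T)
    pos = np.flatnonzero(vals > 0)
    if pos.size == 0:
        raise NoNicheError(f"no temperature permits positive growth at R={R}")
    i0, i1 = pos[0], pos[-1]
    if i0 == 0 or i1 == len(T) - 1:
        raise NoNicheError("growth region not bracketed by the scan window; widen `scan`")
    tmin = brentq(g, T[i0 - 1], T[i0], xtol=ROOT_XTOL)
    tmax = brentq(g, T[i1], T[i1 + 1], xtol=ROOT_XTOL)
    return float(tmin), float(tmax)


def optimal_temperature(R, cp: ConsumerParams) -> float:
    """Temperature maximising per-unit growth at resource density R.

    Located by bounded scalar minimisation inside (Tmin, Tmax); always below
    ``T_I`` because rising respiration drags the growth optimum to cooler
    temperatures than the ingestion optimum.  Raises
    :class:`NoNicheError` when the TPC is nowhere positive.
    """
    tmin, tmax = thermal_limits(R, cp)
    g = _growth_in_T(R, cp)
    res = minimize_scalar(lambda T: -g(T), bounds=(tmin, tmax), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


@dataclass(frozen=True)
class NicheEnvelope:
    """The consumer's (T, R) growth envelope.

    Attributes
    ----------
    boundary
        Array of shape (n, 2): ordered (T, R*(T)) points on the ZNGI.
    topt_ridge
        Array of shape (m, 2): (R, Topt(R)) pairs tracing the growth-optimum
        ridge inside the envelope.
    collapse_point
        ``(T*, R*_min)`` where Tmin and Tmax converge — the minimum of the
        ZNGI, i.e. the lowest resource density at which the consumer can
        grow at any temperature.
    """

    boundary: np.ndarray
    topt_ridge: np.ndarray
    collapse_point: tuple[float, float]


def niche_envelope(cp: ConsumerParams, T_grid=None, n_ridge: int = 40,
                   ridge_R_max: float | None = None) -> NicheEnvelope:
    """Assemble the consumer's thermal-niche envelope over a temperature grid.

    Raises :class:`NoNicheError` if no grid temperature is feasible and
    ``ValueError`` if the envelope is degenerate (growth positive at the
    scan edges, so the ZNGI has no roots to trace).
    """
    if T_grid is None:
        T_grid = np.arange(SCAN_RANGE[0], SCAN_RANGE[1] + SCAN_STEP / 2, SCAN_STEP)
    T_grid = np.asarray(T_grid, dtype=float)
    R = rstar(T_grid, cp)
    feasible = np.isfinite(R)
    if not feasible.any():
        raise NoNicheError("empty envelope: no grid temperature permits consumer growth")
    if feasible[0] or feasible[-1]:
        raise ValueError("degenerate envelope: feasible region reaches the grid edge "
                         "(ZNGI unbounded on this grid)")
    boundary = np.column_stack([T_grid[feasible], R[feasible]])

    # collapse point: minimum of R*(T), refined off-grid
    tlo, thi = boundary[0, 0], boundary[-1, 0]
    res = minimize_scalar(lambda T: rstar(T, cp), bounds=(tlo, thi), method="bounded",
                          options={"xatol": 1e-10})
    collapse = (float(res.x), float(res.fun))

    if ridge_R_max is None:
        ridge_R_max = 200.0 * cp.R_0
    ridge_R = np.geomspace(collapse[1] * 1.02, ridge_R_max, n_ridge)
    ridge = np.column_stack([ridge_R, [optimal_temperature(r, cp) for r in ridge_R]])
    return NicheEnvelope(boundary=boundary, topt_ridge=ridge, collapse_point=collapse)


def realized_tpc(T_grid, cp: ConsumerParams, rt: ResourceTraits):
    """Realized thermal performance curve under resource feedback.

    Consumer invasion growth at the resource-only equilibrium:
    ``consumer_percap_growth(max(K(T), 0), T)``, which equals ``-m(T)``
    wherever the resource itself cannot persist (K <= 0).  This is the curve
    whose sign determines the consumer-persistence boundaries of the
    coupled logistic system.  Returns an array of per-unit growth rates
    aligned with ``T_grid``.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    K = np.maximum(carrying_capacity(T_grid, rt, cp.T_I), 0.0)
    return consumer_percap_growth(K, T_grid, cp)
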