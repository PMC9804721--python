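"""Rosenzweig–MacArthur dynamics with a thermally sensitive logistic resource.

    dR/dt = r(T) * R - gamma * R^2 - f(R, T) * C
    dC/dt = C * [(1 - delta) * f(R, T) - m(T)]

The resource term is the logistic ``r R (1 - R/K)`` rewritten with
``K = r / gamma``, which removes the removable singularity at r = 0 and
automatically gives correct extinction dynamics when r < 0 (density
dependence keeps pushing the population down).  Equilibria: trivial (0, 0);
resource-only (K, 0) reported only where r > 0 (a negative K is never an
equilibrium); coexistence (R*, C_hat) with
``C_hat = (r - gamma R*) (R* + R_0) / Imax`` where R* is feasible and below
K.  Unlike the chemostat, the coexistence point can lose stability through a
Hopf bifurcation: the Jacobian trace vanishes exactly where K(T) crosses
``R_0 ((1-delta) Imax + m) / ((1-delta) Imax - m)`` (equivalently, where the
equilibrium sits at the hump of the resource nullcline at R = (K - R_0)/2),
producing predator–prey limit cycles — the paradox of enrichment expressed
along the temperature axis.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .niche_geometry import rstar
from .records import (COEXISTENCE, RESOURCE_ONLY, TRIVIAL, Bifurcation,
                      EquilibriumBranch, EquilibriumRecord)
from .thermal_rates import (ConsumerParams, ResourceTraits, carrying_capacity,
                            functional_response, max_ingestion, respiration,
                            resource_intrinsic_rate)

__all__ = ["logistic_rhs", "logistic_equilibria", "hopf_points",
           "hopf_threshold_capacity", "logistic_branch_scan"]


def logistic_rhs(state, T: float, cp: ConsumerParams, rt: ResourceTraits):
    """Right-hand side (dR/dt, dC/dt); raises ``ValueError`` on negative state."""
    R, C = state
    if R < 0 or C < 0:
        raise ValueError(f"state must be nonnegative, got (R={R}, C={C})")
    r = resource_intrinsic_rate(T, rt, cp.T_I)
    f = functional_response(R, T, cp)
    return (r * R - rt.gamma * R * R - f * C,
            C * ((1.0 - cp.delta) * f - respiration(T, cp)))


def _fprime(R: float, T: float, cp: ConsumerParams) -> float:
    return max_ingestion(T, cp) * cp.R_0 / (R + cp.R_0) ** 2


def _jacobian(R: float, C: float, T: float, cp: ConsumerParams,
              rt: ResourceTraits) -> np.ndarray:
    r = resource_intrinsic_rate(T, rt, cp.T_I)
    f = functional_response(R, T, cp)
    fp = _fprime(R, T, cp)
    g = (1.0 - cp.delta) * f - respiration(T, cp)
    return np.array([[r - 2.0 * rt.gamma * R - fp * C, -f],
                     [(1.0 - cp.delta) * fp * C, g]])


def _record(R, C, label, T, cp, rt) -> EquilibriumRecord:
    eig = np.linalg.eigvals(_jacobian(float(R), float(C), float(T), cp, rt))
    return EquilibriumRecord(T=float(T), R_hat=float(R), C_hat=float(C), label=label,
                             stable=bool(np.max(eig.real) < 0),
                             eigenvalues=(complex(eig[0]), complex(eig[1])))


def _coexistence_state(T: float, cp: ConsumerParams, rt: ResourceTraits):
    """(R*, C_hat) if the coexistence equilibrium is feasible at T, else None."""
    Rh = rstar(T, cp)
    if not np.isfinite(Rh):
        return None
    r = resource_intrinsic_rate(T, rt, cp.T_I)
    Ch = (r - rt.gamma * Rh) * (Rh + cp.R_0) / max_ingestion(T, cp)
    if Ch <= 0:  # K below the ZNGI: consumer cannot invade
        return None
    return float(Rh), float(Ch)


def logistic_equilibria(T: float, cp: ConsumerParams,
                        rt: ResourceTraits) -> list[EquilibriumRecord]:
    """All equilibria at temperature T: trivial always; resource-only where
    r(T) > 0; coexistence where R* is feasible with positive consumer density."""
    out = [_record(0.0, 0.0, TRIVIAL, T, cp, rt)]
    r = resource_intrinsic_rate(T, rt, cp.T_I)
    if r > 0:
        out.append(_record(r / rt.gamma, 0.0, RESOURCE_ONLY, T, cp, rt))
    coex = _coexistence_state(T, cp, rt)
    if coex is not None:
        out.append(_record(coex[0], coex[1], COEXISTENCE, T, cp, rt))
    return out


def hopf_threshold_capacity(T, cp: ConsumerParams):
    """Carrying capacity at which the coexistence equilibrium loses stability.

    Closed form ``R_0 * ((1-delta) Imax + m) / ((1-delta) Imax - m)``; the
    coexistence trace is positive exactly where K(T) exceeds this (standard
    Rosenzweig–MacArthur enrichment threshold, equivalent to the equilibrium
    sitting left of the nullcline hump at ``(K - R_0)/2``).  NaN where the
    consumer is infeasible even under saturation.
    """
    T = np.asarray(T, dtype=float)
    half = (1.0 - cp.delta) * max_ingestion(T, cp)
    m = respiration(T, cp)
    den = half - m
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, cp.R_0 * (half + m) / np.where(den > 0, den, 1.0), np.nan)
    return out if out.ndim else float(out)


def _coexistence_trace(T: float, cp: ConsumerParams, rt: ResourceTraits) -> float:
    """Trace of the coexistence Jacobian at T; NaN where coexistence infeasible."""
    coex = _coexistence_state(T, cp, rt)
    if coex is None:
        return np.nan
    J = _jacobian(coex[0], coex[1], T, cp, rt)
    return float(J[0, 0] + J[1, 1])


def hopf_points(T_grid, cp: ConsumerParams, rt: ResourceTraits,
                refine_xtol: float = 1e-8) -> list[float]:
    """Temperatures where the coexistence equilibrium changes stability via a
    Hopf bifurcation: zero crossings of the Jacobian trace (with positive
    determinant, automatic at coexistence), detected on the grid and refined
    by Brent's method.  Empty list when the trace never changes sign."""
    T_grid = np.asarray(T_grid, dtype=float)
    tr = np.array([_coexistence_trace(T, cp, rt) for T in T_grid])
    out = []
    ok = np.isfinite(tr[:-1]) & np.isfinite(tr[1:])
    for i in np.flatnonzero(ok & (np.sign(tr[:-1]) * np.sign(tr[1:]) < 0)):
        Tb = brentq(lambda T: _coexistence_trace(T, cp, rt),
                    T_grid[i], T_grid[i + 1], xtol=refine_xtol)
        out.append(float(Tb))
    return out


def logistic_branch_scan(T_grid, cp: ConsumerParams, rt: ResourceTraits,
                         refine_xtol: float = 1e-6) -> EquilibriumBranch:
    """All three equilibrium branches over a monotone temperature grid.

    Transcritical bifurcations are attached where r(T) = 0 (trivial <->
    resource-only exchange) and where K(T) = R*(T) (resource-only <->
    coexistence exchange, i.e. the consumer's realized thermal limits);
    Hopf points from :func:`hopf_points`.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    branch = EquilibriumBranch(model="logistic")
    for T in T_grid:
        branch.records.extend(logistic_equilibria(float(T), cp, rt))

    r = resource_intrinsic_rate(T_grid, rt, cp.T_I)
    for i in np.flatnonzero(np.sign(r[:-1]) * np.sign(r[1:]) < 0):
        Tb = brentq(lambda T: resource_intrinsic_rate(T, rt, cp.T_I),
                    T_grid[i], T_grid[i + 1], xtol=refine_xtol)
        branch.bifurcations.append(Bifurcation(T=float(Tb), kind="transcritical"))

    # invasion margin K - R*: sign change = consumer persistence boundary
    K = carrying_capacity(T_grid, rt, cp.T_I)
    Rs = rstar(T_grid, cp)
    margin = np.where(np.isfinite(Rs) & (r > 0), K - Rs, -1.0)

    def _margin(T):
        Rh = rstar(T, cp)
        if not np.isfinite(Rh):
            return -1.0
        return carrying_capacity(T, rt, cp.T_I) - Rh

    for i in np.flatnonzero(np.sign(margin[:-1]) * np.sign(margin[1:]) < 0):
        Tb = brentq(_margin, T_grid[i], T_grid[i + 1], xtol=refine_xtol)
        branch.bifurcations.append(Bifurcation(T=float(Tb), kind="transcritical"))

    for Th in hopf_points(T_grid, cp, rt):
        branch.bifurcations.append(Bifurcation(T=float(Th), kind="hopf"))
    branch.bifurcations.sort(key=lambda b: b.T)
    return branch
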