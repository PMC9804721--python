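"""Chemostat-supplied resource coupled to a thermally sensitive consumer.

Resources are abiotic nutrients supplied at inflow density S and dilution
rate D, neither sensitive to temperature:

    dR/dt = D * (S - R) - f(R, T) * C
    dC/dt = C * [(1 - delta) * f(R, T) - m(T)]

The system has a resource-only equilibrium (S, 0) and, where the consumer's
R* is feasible and below S, a coexistence equilibrium (R*, C_hat) with
``C_hat = D * (S - R*) * (R* + R_0) / (Imax(T) * R*)``.  The coexistence
equilibrium is always stable where it exists (Jacobian trace
``-D - f'(R*) C_hat < 0`` and determinant > 0), so the only bifurcations on
a temperature sweep are the two transcritical points where consumer
invasion growth at R = S changes sign — the consumer's realized thermal
limits under chemostat supply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterError
from .niche_geometry import rstar
from .records import (COEXISTENCE, RESOURCE_ONLY, Bifurcation,
                      EquilibriumBranch, EquilibriumRecord)
from .thermal_rates import (ConsumerParams, consumer_percap_growth,
                            functional_response, max_ingestion, respiration)

__all__ = ["ChemostatParams", "chemostat_rhs", "chemostat_equilibria",
           "chemostat_branch_scan"]


@dataclass(frozen=True)
class ChemostatParams:
    """Chemostat supply: inflow resource density S and flow rate D (both > 0,
    temperature-independent)."""

    S: float = 1.0
    D: float = 1.0

    def __post_init__(self):
        bad = [f"{k} must be > 0, got {v}" for k, v in (("S", self.S), ("D", self.D))
               if not v > 0]
        if bad:
            raise ParameterError("ChemostatParams: " + "; ".join(bad))


def _fprime(R: float, T: float, cp: ConsumerParams) -> float:
    """dF/dR of the type II response: Imax * R_0 / (R + R_0)^2."""
    return max_ingestion(T, cp) * cp.R_0 / (R + cp.R_0) ** 2


def chemostat_rhs(state, T: float, cp: ConsumerParams, chp: ChemostatParams):
    """Right-hand side (dR/dt, dC/dt) of the chemostat system."""
    R, C = state
    if R < 0 or C < 0:
        raise ValueError(f"state must be nonnegative, got (R={R}, C={C})")
    f = functional_response(R, T, cp)
    return (chp.D * (chp.S - R) - f * C,
            C * ((1.0 - cp.delta) * f - respiration(T, cp)))


def _jacobian(R: float, C: float, T: float, cp: ConsumerParams,
              chp: ChemostatParams) -> np.ndarray:
    f = functional_response(R, T, cp)
    fp = _fprime(R, T, cp)
    g = (1.0 - cp.delta) * f - respiration(T, cp)
    return np.array([[-chp.D - fp * C, -f],
                     [(1.0 - cp.delta) * fp * C, g]])


def _record(R: float, C: float, label: str, T: float, cp, chp) -> EquilibriumRecord:
    eig = np.linalg.eigvals(_jacobian(R, C, T, cp, chp))
    return EquilibriumRecord(T=float(T), R_hat=float(R), C_hat=float(C), label=label,
                             stable=bool(np.max(eig.real) < 0),
                             eigenvalues=(complex(eig[0]), complex(eig[1])))


def chemostat_equilibria(T: float, cp: ConsumerParams,
                         chp: ChemostatParams) -> list[EquilibriumRecord]:
    """All equilibria at temperature T with eigenvalues and stability.

    Always contains the resource-only equilibrium (S, 0); adds the
    coexistence equilibrium whenever R*(T) is feasible and below S.
    """
    out = [_record(chp.S, 0.0, RESOURCE_ONLY, T, cp, chp)]
    Rh = rstar(T, cp)
    if np.isfinite(Rh) and Rh < chp.S:
        Ch = chp.D * (chp.S - Rh) * (Rh + cp.R_0) / (max_ingestion(T, cp) * Rh)
        out.append(_record(Rh, Ch, COEXISTENCE, T, cp, chp))
    return out


def invasion_growth(T, cp: ConsumerParams, chp: ChemostatParams):
    """Consumer per-unit growth when rare, at the resource-only equilibrium R = S."""
    return consumer_percap_growth(chp.S, T, cp)


def chemostat_branch_scan(T_grid, cp: ConsumerParams, chp: ChemostatParams,
                          refine_xtol: float = 1e-6) -> EquilibriumBranch:
    """Equilibrium branches over a monotone temperature grid.

    Transcritical bifurcations (consumer invasion/extinction boundaries) are
    located by sign changes of invasion growth at R = S, refined by Brent's
    method to ``refine_xtol`` degC.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    branch = EquilibriumBranch(model="chemostat")
    for T in T_grid:
        branch.records.extend(chemostat_equilibria(float(T), cp, chp))
    inv = invasion_growth(T_grid, cp, chp)
    for i in np.flatnonzero(np.sign(inv[:-1]) * np.sign(inv[1:]) < 0):
        Tb = brentq(lambda T: invasion_growth(T, cp, chp),
                    T_grid[i], T_grid[i + 1], xtol=refine_xtol)
        branch.bifurcations.append(Bifurcation(T=float(Tb), kind="transcritical"))
    return branch
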