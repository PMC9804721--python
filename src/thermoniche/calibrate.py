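"""Calibration searches for the resource-trait stand-ins.

Two searches back the shipped fixtures:

* :func:`min_density_dependence` — the smallest density-dependence strength
  gamma for which the coexistence equilibrium never loses stability (no
  Hopf points) for a given consumer, across the whole mismatch lattice.
  The worst case at each temperature is a resource whose growth ridge is
  aligned there, so the bound is ``max_T r_ridge(T) / K_hopf(T)``.
* :func:`find_mismatch_fixtures` — the smallest integer |delta_T| on each
  side whose realized niche edge clears the ZNGI minimum temperature by a
  required margin: the meltdown fixture (negative side, realized Tmax on
  the negative-sloping ZNGI flank) and its mirror (positive side, realized
  Tmin on the positive-sloping flank).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import NoCoexistenceError
from .logistic_model import hopf_threshold_capacity
from .niche_geometry import rstar, thermal_limits
from .regime_mapper import realized_niche_limits
from .thermal_rates import ConsumerParams, ResourceTraits

__all__ = ["min_density_dependence", "find_mismatch_fixtures", "zngi_minimum"]


def zngi_minimum(cp: ConsumerParams) -> tuple[float, float]:
    """(T*, R*_min): location and value of the minimum of the consumer ZNGI."""
    lo, hi = thermal_limits(np.inf, cp)
    res = minimize_scalar(lambda T: rstar(T, cp), bounds=(lo + 1e-9, hi - 1e-9),
                          method="bounded", options={"xatol": 1e-10})
    return float(res.x), float(res.fun)


def min_density_dependence(cp: ConsumerParams, rt: ResourceTraits,
                           n: int = 20000) -> float:
    """Smallest gamma guaranteeing no Hopf bifurcation for this consumer at
    any mismatch: ``max_T r_ridge(T) / K_hopf(T)`` over the consumer's
    fundamental thermal range, where ``r_ridge(T) = b_max - d_0 - d_1 e^{d_2 T}``
    is the intrinsic rate when the resource optimum is aligned at T."""
    lo, hi = thermal_limits(np.inf, cp)
    T = np.linspace(lo + 1e-6, hi - 1e-6, n)
    r_ridge = rt.b_max - rt.d_0 - rt.d_1 * np.exp(rt.d_2 * T)
    Kh = hopf_threshold_capacity(T, cp)
    with np.errstate(invalid="ignore"):
        ratio = np.where(np.isfinite(Kh) & (r_ridge > 0), r_ridge / Kh, -np.inf)
    return float(np.max(ratio))


def find_mismatch_fixtures(cp: ConsumerParams, rt: ResourceTraits, *,
                           clearance: float = 2.0,
                           dT_limit: float = 40.0) -> dict[str, float]:
    """Integer-step search for the calibrated mismatch fixtures.

    Returns ``{"meltdown_delta_T": ..., "mirror_delta_T": ...}`` — on each
    side, the smallest integer |delta_T| whose realized edge (Tmax on the
    negative side, Tmin on the positive) clears the ZNGI minimum temperature
    T* by at least ``clearance`` degC while a coexistence band still exists.
    """
    t_star, _ = zngi_minimum(cp)
    out: dict[str, float] = {}

    def edge(dT: float):
        try:
            return realized_niche_limits(cp, replace(rt, delta_T=dT))
        except NoCoexistenceError:
            return None

    for sign, key in ((-1.0, "meltdown_delta_T"), (+1.0, "mirror_delta_T")):
        for k in range(1, int(dT_limit) + 1):
            band = edge(sign * k)
            if band is None:
                break
            tmin, tmax = band
            if sign < 0 and tmax <= t_star - clearance:
                out[key] = -float(k)
                break
            if sign > 0 and tmin >= t_star + clearance:
                out[key] = float(k)
                break
    return out
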