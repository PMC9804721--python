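"""Thermal-mismatch analysis for the logistic-resource model.

The signed mismatch ``delta_T`` shifts the resource's growth optimum
relative to the consumer's ingestion optimum.  Sweeping (delta_T, T)
classifies every cell by its stable attractor (extinct / resource-only /
stable coexistence / coexistence cycles), traces how the consumer's
realized thermal limits are re-set by resource thermal traits, and flags
the "metabolic meltdown" configuration: when the realized Tmax falls on the
negative-sloping (cold) flank of the consumer's ZNGI, equilibrium resource
density *declines* as warming pushes the consumer toward its realized Tmax
— warming and resource scarcity then compound instead of the usual
relaxation of top-down control.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .errors import NoCoexistenceError, NoNicheError
from .logistic_model import logistic_equilibria
from .niche_geometry import SCAN_RANGE, SCAN_STEP, realized_tpc, rstar, thermal_limits
from .records import COEXISTENCE, RESOURCE_ONLY
from .thermal_rates import (ConsumerParams, ResourceTraits, carrying_capacity,
                            resource_intrinsic_rate)

__all__ = ["classify_regime", "regime_grid", "meltdown_report", "tpc_family",
           "realized_niche_limits", "RegimeGrid", "MeltdownReport",
           "EXTINCT", "RESOURCE_ONLY_REGIME", "COEXIST_STABLE", "COEXIST_CYCLES"]

EXTINCT = "extinct"
RESOURCE_ONLY_REGIME = "resource_only"
COEXIST_STABLE = "coexist_stable"
COEXIST_CYCLES = "coexist_cycles"

CONSUMER_PHYSIOLOGY = "consumer_physiology"
RESOURCE_THERMAL_TRAITS = "resource_thermal_traits"


def _shifted(rt: ResourceTraits, delta_T: float) -> ResourceTraits:
    return replace(rt, delta_T=delta_T)


def classify_regime(T: float, delta_T: float, cp: ConsumerParams,
                    rt: ResourceTraits) -> str:
    """Stable-attractor label at (T, delta_T), with ``rt`` shifted to the
    given mismatch.  Cycles are inferred from an existing-but-unstable
    coexistence equilibrium (supercritical Hopf regime)."""
    recs = logistic_equilibria(T, cp, _shifted(rt, delta_T))
    by_label = {r.label: r for r in recs}
    if RESOURCE_ONLY not in by_label:
        return EXTINCT
    if COEXISTENCE not in by_label:
        return RESOURCE_ONLY_REGIME
    return COEXIST_STABLE if by_label[COEXISTENCE].stable else COEXIST_CYCLES


@dataclass(frozen=True)
class RegimeGrid:
    """Classification of the dynamical outcome over a (delta_T, T) lattice.

    ``labels[i, j]`` is the regime at ``(delta_T_axis[i], T_axis[j])``.
    """

    delta_T_axis: np.ndarray
    T_axis: np.ndarray
    labels: np.ndarray  # dtype=object, shape (len(delta_T_axis), len(T_axis))

    def realized_limits(self, delta_T: float) -> tuple[float, float] | None:
        """Grid-resolution (Tmin, Tmax) of the coexistence band at one mismatch."""
        i = int(np.argmin(np.abs(self.delta_T_axis - delta_T)))
        coex = np.flatnonzero(np.isin(self.labels[i], [COEXIST_STABLE, COEXIST_CYCLES]))
        if coex.size == 0:
            return None
        return float(self.T_axis[coex[0]]), float(self.T_axis[coex[-1]])

    def to_frame(self) -> pd.DataFrame:
        """Long-format (delta_T, T_C, label) table."""
        dT, T = np.meshgrid(self.delta_T_axis, self.T_axis, indexing="ij")
        return pd.DataFrame({"delta_T": dT.ravel(), "T_C": T.ravel(),
                             "label": self.labels.ravel()})


def regime_grid(T_grid, delta_T_grid, cp: ConsumerParams,
                rt: ResourceTraits) -> RegimeGrid:
    """Classify every (delta_T, T) cell; axes must be monotone."""
    T_grid = np.asarray(T_grid, dtype=float)
    delta_T_grid = np.asarray(delta_T_grid, dtype=float)
    labels = np.empty((delta_T_grid.size, T_grid.size), dtype=object)
    for i, dT in enumerate(delta_T_grid):
        for j, T in enumerate(T_grid):
            labels[i, j] = classify_regime(float(T), float(dT), cp, rt)
    return RegimeGrid(delta_T_axis=delta_T_grid, T_axis=T_grid, labels=labels)


def realized_niche_limits(cp: ConsumerParams, rt: ResourceTraits,
                          scan=SCAN_RANGE, step: float = SCAN_STEP) -> tuple[float, float]:
    """Realized (Tmin, Tmax): the boundary of positive consumer invasion
    growth at the resource-only equilibrium, refined by Brent's method on
    the invasion margin K(T) - R*(T).  Raises :class:`NoCoexistenceError`
    when the consumer can invade nowhere."""
    T = np.arange(scan[0], scan[1] + step / 2, step)
    K = carrying_capacity(T, rt, cp.T_I)
    Rs = rstar(T, cp)
    ok = np.isfinite(Rs) & (K > 0)
    margin = np.where(ok, K - np.where(np.isfinite(Rs), Rs, np.inf), -1.0)
    pos = np.flatnonzero(margin > 0)
    if pos.size == 0:
        raise NoCoexistenceError("consumer cannot invade at any temperature "
                                 "for this parameterization")

    def _margin(Tq):
        Rh = rstar(Tq, cp)
        if not np.isfinite(Rh):
            return -1.0
        return carrying_capacity(Tq, rt, cp.T_I) - Rh

    i0, i1 = pos[0], pos[-1]
    tmin = brentq(_margin, T[i0 - 1], T[i0], xtol=1e-8) if i0 > 0 else float(T[0])
    tmax = brentq(_margin, T[i1], T[i1 + 1], xtol=1e-8) if i1 < T.size - 1 else float(T[-1])
    return float(tmin), float(tmax)


@dataclass(frozen=True)
class MeltdownReport:
    """Realized thermal limits, what sets them, and the meltdown verdict.

    ``slope_at_tmin``/``slope_at_tmax`` are the signs (+1/-1) of dR*/dT at
    the approach to each realized edge.  ``meltdown`` is True exactly when
    the realized Tmax lies below the temperature minimising R*(T), so the
    equilibrium resource density declines as warming pushes the consumer
    toward its realized upper limit.
    """

    t_min: float
    t_max: float
    limiting_factor_tmin: str
    limiting_factor_tmax: str
    slope_at_tmin: int
    slope_at_tmax: int
    meltdown: bool
    zngi_min_T: float


def meltdown_report(cp: ConsumerParams, rt: ResourceTraits, *,
                    edge_tol: float = 0.1) -> MeltdownReport:
    """Diagnose which side of the ZNGI the realized limits fall on.

    Each edge is tagged ``consumer_physiology`` if it coincides (within
    ``edge_tol`` degC) with the corresponding root of the saturated net
    gain ``(1-delta) Imax - m`` (the fundamental thermal limit), else
    ``resource_thermal_traits``.  Raises :class:`NoCoexistenceError` when
    there is no coexistence band.
    """
    tmin, tmax = realized_niche_limits(cp, rt)
    sat_min, sat_max = thermal_limits(np.inf, cp)

    res = minimize_scalar(lambda T: rstar(T, cp), bounds=(sat_min + 1e-9, sat_max - 1e-9),
                          method="bounded", options={"xatol": 1e-10})
    t_star = float(res.x)

    def slope_sign(T_edge: float, inward: float) -> int:
        h = 1e-4
        d = (rstar(T_edge + inward * h, cp) - rstar(T_edge + inward * 2 * h, cp)) / (-inward * h)
        return int(np.sign(d)) if np.isfinite(d) else 0

    return MeltdownReport(
        t_min=tmin, t_max=tmax,
        limiting_factor_tmin=(CONSUMER_PHYSIOLOGY if abs(tmin - sat_min) <= edge_tol
                              else RESOURCE_THERMAL_TRAITS),
        limiting_factor_tmax=(CONSUMER_PHYSIOLOGY if abs(tmax - sat_max) <= edge_tol
                              else RESOURCE_THERMAL_TRAITS),
        slope_at_tmin=slope_sign(tmin, +1.0),
        slope_at_tmax=slope_sign(tmax, -1.0),
        meltdown=bool(tmax < t_star),
        zngi_min_T=t_star,
    )


def tpc_family(delta_T_list, cp: ConsumerParams, rt: ResourceTraits,
               T_grid) -> pd.DataFrame:
    """Realized TPCs for a family of mismatches, stacked long-format.

    Columns: ``delta_T``, ``T_C``, ``growth``.  Every curve is bounded above
    by the fundamental (resource-saturated) TPC because the functional
    response increases with R.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    frames = []
    for dT in delta_T_list:
        g = realized_tpc(T_grid, cp, _shifted(rt, float(dT)))
        frames.append(pd.DataFrame({"delta_T": float(dT), "T_C": T_grid, "growth": g}))
    return pd.concat(frames, ignore_index=True)
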