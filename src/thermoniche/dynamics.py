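"""Time integration, limit-cycle summaries and consumer turnover.

Shared by both resource-supply models.  Integrations are deterministic
(stiff-safe LSODA with tight tolerances); nonnegativity of the reported
states is enforced by clipping solver round-off below zero at an absolute
tolerance of 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .chemostat_model import ChemostatParams, chemostat_equilibria, chemostat_rhs
from .errors import IntegrationError, NoCoexistenceError
from .logistic_model import logistic_equilibria, logistic_rhs
from .records import COEXISTENCE
from .thermal_rates import ConsumerParams, ResourceTraits, functional_response

__all__ = ["Trajectory", "CycleSummary", "integrate", "cycle_summary",
           "consumer_turnover", "equilibria_for"]

_CLIP = 1e-12


def _rhs_for(model: str):
    if model == "chemostat":
        return chemostat_rhs
    if model == "logistic":
        return logistic_rhs
    raise ValueError(f"unknown model {model!r}; expected 'chemostat' or 'logistic'")


def equilibria_for(model: str, T: float, cp: ConsumerParams, params):
    """Dispatch to the model-appropriate equilibrium solver."""
    if model == "chemostat":
        return chemostat_equilibria(T, cp, params)
    if model == "logistic":
        return logistic_equilibria(T, cp, params)
    raise ValueError(f"unknown model {model!r}; expected 'chemostat' or 'logistic'")


@dataclass(frozen=True)
class Trajectory:
    """A simulated orbit: strictly increasing times and nonnegative (R, C) states."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 2)
    model: str
    T: float

    @property
    def R(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def C(self) -> np.ndarray:
        return self.states[:, 1]


@dataclass(frozen=True)
class CycleSummary:
    """Post-transient extrema of a simulated attractor.

    At a stable equilibrium all four extrema collapse onto the equilibrium
    densities; on a limit cycle they bracket the unstable focus.  ``period``
    is NaN when fewer than two resource peaks are present in the window.
    ``converged`` means the extrema drifted by < 1% between the last two
    half-windows.
    """

    R_min: float
    R_max: float
    C_min: float
    C_max: float
    period: float
    converged: bool

    @property
    def amplitude_R(self) -> float:
        return self.R_max - self.R_min


def integrate(model: str, T: float, init, t_end: float,
              cp: ConsumerParams, params, *, n_points: int = 2000,
              t_start: float = 0.0, rtol: float = 1e-9,
              atol: float = 1e-11) -> Trajectory:
    """Integrate the chosen model from ``init = (R, C)`` up to ``t_end``.

    ``params`` is a :class:`ChemostatParams` or :class:`ResourceTraits` to
    match ``model``.  Raises :class:`IntegrationError` with solver
    diagnostics on failure.
    """
    R0, C0 = init
    if R0 < 0 or C0 < 0:
        raise ValueError(f"initial state must be nonnegative, got {init}")
    rhs = _rhs_for(model)

    def f(t, y):
        return rhs(np.maximum(y, 0.0), T, cp, params)

    sol = solve_ivp(f, (t_start, t_end), [R0, C0], method="LSODA",
                    t_eval=np.linspace(t_start, t_end, n_points),
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"solver failed at T={T}: {sol.message}",
                               diagnostics={"status": sol.status, "message": sol.message,
                                            "nfev": sol.nfev, "t_reached": sol.t[-1] if sol.t.size else None})
    states = sol.y.T.copy()
    if states.min() < -1e3 * atol:  # genuine escape, not round-off
        raise IntegrationError(
            f"state went negative beyond tolerance at T={T} (min {states.min():.3e})",
            diagnostics={"min_state": float(states.min())})
    states = np.maximum(states, 0.0)
    return Trajectory(times=sol.t, states=states, model=model, T=float(T))


def _coexistence_record(model, T, cp, params):
    recs = [r for r in equilibria_for(model, T, cp, params) if r.label == COEXISTENCE]
    if not recs:
        raise NoCoexistenceError(f"no coexistence equilibrium at T={T} ({model})")
    return recs[0]


def cycle_summary(model: str, T: float, cp: ConsumerParams, params, *,
                  transient: float = 2000.0, window: float = 500.0,
                  init=None, drift_tol: float = 0.01) -> CycleSummary:
    """Attractor summary at temperature T after discarding a transient.

    Starts from a 5% perturbation of the coexistence equilibrium unless
    ``init`` is given, integrates ``transient + window`` time units and
    reports extrema over the final window.  ``converged`` compares extrema
    across the two halves of the window (< ``drift_tol`` relative drift);
    non-convergence is reported in the flag, never silently dropped.
    Raises :class:`NoCoexistenceError` when coexistence is infeasible at T.
    """
    eq = _coexistence_record(model, T, cp, params)
    if init is None:
        init = (1.05 * eq.R_hat, 1.05 * eq.C_hat)
    traj = integrate(model, T, init, transient + window, cp, params,
                     n_points=max(4000, int(window * 20)))
    mask = traj.times >= transient
    t, R, C = traj.times[mask], traj.R[mask], traj.C[mask]

    halves = [slice(0, len(t) // 2), slice(len(t) // 2, None)]
    ext = np.array([[R[h].min(), R[h].max(), C[h].min(), C[h].max()] for h in halves])
    scale = max(eq.R_hat, eq.C_hat, 1e-12)
    converged = bool(np.all(np.abs(ext[1] - ext[0]) <= drift_tol * scale))

    peaks, _ = find_peaks(R)
    period = float(np.mean(np.diff(t[peaks]))) if peaks.size >= 2 else float("nan")
    return CycleSummary(R_min=float(R.min()), R_max=float(R.max()),
                        C_min=float(C.min()), C_max=float(C.max()),
                        period=period, converged=converged)


def consumer_turnover(T: float, cp: ConsumerParams, params, model: str) -> float:
    """Consumer production/biomass ratio at the coexistence equilibrium.

    Per-unit gross production ``(1 - delta) * f(R_hat, T)``, which at any
    coexistence equilibrium equals the respiration rate m(T) — so turnover
    rises roughly exponentially with warming along a branch and is lowest at
    the branch's cold end.  Raises :class:`NoCoexistenceError` where
    coexistence is infeasible.
    """
    eq = _coexistence_record(model, T, cp, params)
    return float((1.0 - cp.delta) * functional_response(eq.R_hat, T, cp))
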