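"""Temperature-dependent vital rates for the consumer and the resource.

The consumer is a heterotroph in the Yodzis–Innes biomass formalism: its
per-unit growth is assimilated ingestion minus respiration,

    dC/(C dt) = (1 - delta) * f(R, T) - m(T),

with a Michaelis–Menten (Holling type II) functional response
``f(R, T) = Imax(T) * R / (R + R_0)``, a Gaussian peak for the maximum
ingestion rate ``Imax(T) = exp(-(T - T_I)^2 / beta)`` and an exponential
respiration rate ``m(T) = m_a * exp(m_b * T) + m_c`` (a smooth stand-in for
the Boltzmann–Arrhenius rise over the biologically relevant range).

The biotic resource grows logistically with temperature-dependent intrinsic
rate ``r(T)`` (Gaussian birth minus exponential maintenance) and carrying
capacity ``K(T) = r(T) / gamma``.  Tying K to r through a
temperature-independent density-dependence strength ``gamma`` enforces the
sign constraint that r and K share zeros and sign for every temperature, so
density dependence keeps pushing a declining population down (never rescuing
it) when r < 0.

All temperatures are in degrees Celsius; every function is vectorised over T
(and R where applicable).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .errors import ParameterError

__all__ = [
    "ConsumerParams",
    "ResourceTraits",
    "respiration",
    "max_ingestion",
    "functional_response",
    "consumer_percap_growth",
    "resource_intrinsic_rate",
    "carrying_capacity",
]


def _check(conditions: list[tuple[bool, str]], cls: str) -> None:
    bad = [msg for ok, msg in conditions if not ok]
    if bad:
        raise ParameterError(f"{cls}: " + "; ".join(bad))


@dataclass(frozen=True)
class ConsumerParams:
    """Bioenergetic and thermal traits of the consumer.

    Parameters
    ----------
    delta
        Fraction of ingested biomass lost to assimilation inefficiency
        (dimensionless, ``0 <= delta < 1``); ``1 - delta`` is assimilated.
    m_a, m_b, m_c
        Respiration scale (per time), exponent (per degC) and offset
        (per time) of ``m(T) = m_a * exp(m_b * T) + m_c``; all positive.
    T_I
        Optimum temperature for consumption (degC) — the peak of the maximum
        ingestion rate, not the peak of the growth TPC.
    beta
        Breadth of the ingestion peak (degC^2), positive.
    R_0
        Half-saturation resource density of the functional response
        (resource units), positive.  Equivalent to ``1/(a*h)`` in Holling
        notation; larger values describe a more prudent consumer.
    """

    delta: float = 0.5
    m_a: float = 0.01
    m_b: float = 0.1
    m_c: float = 0.05
    T_I: float = 25.0
    beta: float = 150.0
    R_0: float = 0.5

    def __post_init__(self):
        _check(
            [
                (0.0 <= self.delta < 1.0, f"delta must satisfy 0 <= delta < 1, got {self.delta}"),
                (self.m_a > 0, f"m_a must be > 0, got {self.m_a}"),
                (self.m_b > 0, f"m_b must be > 0, got {self.m_b}"),
                (self.m_c > 0, f"m_c must be > 0, got {self.m_c}"),
                (self.beta > 0, f"beta must be > 0, got {self.beta}"),
                (self.R_0 > 0, f"R_0 must be > 0, got {self.R_0}"),
            ],
            "ConsumerParams",
        )

    # Holling-form accessors: Imax = 1/h and R_0 = 1/(a*h).
    def handling_time(self, T):
        """Holling handling time ``h(T) = 1 / Imax(T)``."""
        return 1.0 / max_ingestion(T, self)

    def attack_rate(self, T):
        """Holling attack rate ``a(T) = Imax(T) / R_0``."""
        return max_ingestion(T, self) / self.R_0


@dataclass(frozen=True)
class ResourceTraits:
    """Thermal traits of a logistically growing biotic resource.

    ``r(T) = b_max * exp(-(T - T_I - delta_T)^2 / beta_r) - (d_0 + d_1 * exp(d_2 * T))``
    and ``K(T) = r(T) / gamma``.  The growth optimum is written relative to
    the consumer's ingestion optimum ``T_I`` (threaded in by the caller) so
    that ``delta_T`` is the signed thermal mismatch between resource and
    consumer; ``beta_r`` defaults to the consumer's breadth but is stored
    independently so breadth mismatch is expressible.

    Defaults are the package's calibrated reference parameterisation; see
    docs/methods.md for the calibration targets.
    """

    b_max: float = 1.0
    delta_T: float = 0.0
    beta_r: float = 150.0
    d_0: float = 0.05
    d_1: float = 0.005
    d_2: float = 0.1
    gamma: float = 0.525

    def __post_init__(self):
        _check(
            [
                (self.b_max > 0, f"b_max must be > 0, got {self.b_max}"),
                (self.beta_r > 0, f"beta_r must be > 0, got {self.beta_r}"),
                (self.d_0 >= 0, f"d_0 must be >= 0, got {self.d_0}"),
                (self.d_1 >= 0, f"d_1 must be >= 0, got {self.d_1}"),
                (self.d_2 > 0, f"d_2 must be > 0, got {self.d_2}"),
                (self.gamma > 0, f"gamma must be > 0, got {self.gamma}"),
            ],
            "ResourceTraits",
        )


def _require_nonnegative_R(R) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("resource density R must be nonnegative")
    return R


def respiration(T, cp: ConsumerParams):
    """Consumer respiration rate ``m(T) = m_a * exp(m_b * T) + m_c`` (per time).

    Strictly positive and strictly increasing in T; tends to ``m_c`` as
    T -> -inf.
    """
    T = np.asarray(T, dtype=float)
    out = cp.m_a * np.exp(cp.m_b * T) + cp.m_c
    return out if out.ndim else float(out)


def max_ingestion(T, cp: ConsumerParams):
    """Maximum ingestion rate ``Imax(T) = exp(-(T - T_I)^2 / beta)``.

    A symmetric unimodal peak in (0, 1], equal to 1 at ``T = T_I``.
    """
    T = np.asarray(T, dtype=float)
    out = np.exp(-((T - cp.T_I) ** 2) / cp.beta)
    return out if out.ndim else float(out)


def functional_response(R, T, cp: ConsumerParams):
    """Type II ingestion rate ``f(R, T) = Imax(T) * R / (R + R_0)`` (per time).

    Zero at ``R = 0``, half of ``Imax`` at ``R = R_0``, saturating to
    ``Imax(T)`` as R -> inf (``R = inf`` is accepted and means saturation).
    Raises ``ValueError`` for negative R.
    """
    R = _require_nonnegative_R(R)
    with np.errstate(invalid="ignore"):
        sat = np.where(np.isinf(R), 1.0, R / (R + cp.R_0))
    out = max_ingestion(T, cp) * sat
    return out if np.ndim(out) else float(out)


def consumer_percap_growth(R, T, cp: ConsumerParams):
    """Per-unit consumer growth ``(1 - delta) * f(R, T) - m(T)`` (per time).

    The demographic TPC at fixed resource density; negative wherever
    assimilated intake cannot cover respiration.
    """
    out = (1.0 - cp.delta) * functional_response(R, T, cp) - respiration(T, cp)
    return out if np.ndim(out) else float(out)


def resource_intrinsic_rate(T, rt: ResourceTraits, T_I: float = 25.0):
    """Resource intrinsic growth rate r(T) (per time).

    Gaussian birth peaked at ``T_I + delta_T`` minus exponentially rising
    maintenance; negative at thermal extremes whenever maintenance is
    nonzero.  ``T_I`` is the paired consumer's ingestion optimum, threaded
    explicitly so the traits object stays self-contained.
    """
    T = np.asarray(T, dtype=float)
    birth = rt.b_max * np.exp(-((T - T_I - rt.delta_T) ** 2) / rt.beta_r)
    death = rt.d_0 + rt.d_1 * np.exp(rt.d_2 * T)
    out = birth - death
    return out if out.ndim else float(out)


def carrying_capacity(T, rt: ResourceTraits, T_I: float = 25.0):
    """Carrying capacity ``K(T) = r(T) / gamma`` (resource units).

    Shares zeros and sign with r(T) by construction.  Negative values are
    legal and meaningful: they encode density dependence that keeps pushing
    a declining population toward extinction under thermal stress (a
    negative K is never a stable equilibrium).
    """
    out = resource_intrinsic_rate(T, rt, T_I) / rt.gamma
    return out if np.ndim(out) else float(out)


def params_to_dict(cp: ConsumerParams | None = None,
                   rt: ResourceTraits | None = None,
                   extra: dict | None = None) -> dict:
    """Flatten parameter objects into the flat key-value config dialect."""
    out: dict = {}
    for obj in (cp, rt):
        if obj is not None:
            out.update({f.name: getattr(obj, f.name) for f in fields(obj)})
    if extra:
        out.update(extra)
    return out
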