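"""Named parameter fixtures reproducing each figure-level scenario.

Provenance matters: the consumer parameters and chemostat supply are printed
values (the figure-caption symbol labels were garbled in the source, so the
mapping m_a=0.01, m_b=0.1, m_c=0.05, T_I=25 is inferred from equation order
— see docs/methods.md).  The resource thermal traits are calibrated
stand-ins: the original parameter list is not legible, so the defaults are
chosen to satisfy the stated scenario (resource fundamental niche wider
than the consumer's; limit cycles for the efficient consumer R_0=0.5 only).
The mismatch values +9 / -18 degC ship verbatim as ``fig5a``/``fig5b``;
``meltdown_calibrated`` / ``mirror_calibrated`` are the values found by
:mod:`thermoniche.calibrate` under the package's calibrated resource traits.
"""

from __future__ import annotations

from dataclasses import replace

from .chemostat_model import ChemostatParams
from .errors import ConfigError
from .thermal_rates import ConsumerParams, ResourceTraits

__all__ = ["get_fixture", "list_fixtures", "BOX1_CONSUMER", "DEFAULT_RESOURCE"]

#: Printed consumer parameterisation (efficient consumer, R_0 = 0.5).
BOX1_CONSUMER = ConsumerParams(delta=0.5, m_a=0.01, m_b=0.1, m_c=0.05,
                               T_I=25.0, beta=150.0, R_0=0.5)

#: Calibrated logistic-resource stand-in (see module docstring).
DEFAULT_RESOURCE = ResourceTraits(b_max=1.0, delta_T=0.0, beta_r=150.0,
                                  d_0=0.05, d_1=0.005, d_2=0.1, gamma=0.525)

_FIXTURES: dict[str, dict] = {
    # Consumption/respiration geometry and the (T, R) niche envelope.
    "box1": {"model": None, "consumer": BOX1_CONSUMER},
    # Chemostat branch scans: efficient vs prudent consumer.
    "fig2": {"model": "chemostat", "consumer": BOX1_CONSUMER,
             "chemostat": ChemostatParams(S=1.0, D=1.0)},
    "fig2_prudent": {"model": "chemostat", "consumer": replace(BOX1_CONSUMER, R_0=2.0),
                     "chemostat": ChemostatParams(S=1.0, D=1.0)},
    # Logistic branch scans at three saturation constants.
    "fig3_r05": {"model": "logistic", "consumer": BOX1_CONSUMER,
                 "resource": DEFAULT_RESOURCE},
    "fig3_r1": {"model": "logistic", "consumer": replace(BOX1_CONSUMER, R_0=1.0),
                "resource": DEFAULT_RESOURCE},
    "fig3_r2": {"model": "logistic", "consumer": replace(BOX1_CONSUMER, R_0=2.0),
                "resource": DEFAULT_RESOURCE},
    # Mismatch regime diagram and TPC family (R_0 = 1).
    "fig4": {"model": "logistic", "consumer": replace(BOX1_CONSUMER, R_0=1.0),
             "resource": DEFAULT_RESOURCE},
    # Printed mismatch scenarios, shipped verbatim for comparison runs.
    "fig5a": {"model": "logistic", "consumer": replace(BOX1_CONSUMER, R_0=1.0),
              "resource": replace(DEFAULT_RESOURCE, delta_T=9.0)},
    "fig5b": {"model": "logistic", "consumer": replace(BOX1_CONSUMER, R_0=1.0),
              "resource": replace(DEFAULT_RESOURCE, delta_T=-18.0)},
    # Calibrated mismatch fixtures (robust meltdown / mirrored Tmin case).
    "meltdown_calibrated": {"model": "logistic",
                            "consumer": replace(BOX1_CONSUMER, R_0=1.0),
                            "resource": replace(DEFAULT_RESOURCE, delta_T=-20.0)},
    "mirror_calibrated": {"model": "logistic",
                          "consumer": replace(BOX1_CONSUMER, R_0=1.0),
                          "resource": replace(DEFAULT_RESOURCE, delta_T=11.0)},
}


def list_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def get_fixture(name: str) -> dict:
    """Return a dict with keys among {model, consumer, resource, chemostat}."""
    try:
        return dict(_FIXTURES[name])
    except KeyError:
        raise ConfigError(f"unknown fixture {name!r}; available: {', '.join(list_fixtures())}") from None
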