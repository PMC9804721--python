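"""Equilibrium bookkeeping shared by the chemostat and logistic models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EquilibriumRecord", "Bifurcation", "EquilibriumBranch",
           "TRIVIAL", "RESOURCE_ONLY", "COEXISTENCE"]

TRIVIAL = "trivial"
RESOURCE_ONLY = "resource_only"
COEXISTENCE = "coexistence"


@dataclass(frozen=True)
class EquilibriumRecord:
    """One equilibrium of the planar consumer-resource system at temperature T.

    ``label`` is one of {trivial, resource_only, coexistence}; ``stable`` is
    the eigenvalue verdict (max real part < 0); ``eigenvalues`` are the two
    (possibly complex) growth rates of the Jacobian.
    """

    T: float
    R_hat: float
    C_hat: float
    label: str
    stable: bool
    eigenvalues: tuple[complex, complex]

    @property
    def max_real_eigenvalue(self) -> float:
        return float(max(ev.real for ev in self.eigenvalues))


@dataclass(frozen=True)
class Bifurcation:
    """A detected bifurcation: temperature plus type tag."""

    T: float
    kind: str  # "transcritical" | "hopf"


@dataclass
class EquilibriumBranch:
    """Equilibria over an ordered temperature grid plus detected bifurcations."""

    model: str
    records: list[EquilibriumRecord] = field(default_factory=list)
    bifurcations: list[Bifurcation] = field(default_factory=list)

    def select(self, label: str) -> list[EquilibriumRecord]:
        return [r for r in self.records if r.label == label]

    def coexistence(self) -> list[EquilibriumRecord]:
        return self.select(COEXISTENCE)

    def stable_at(self, T: float, atol: float = 1e-9) -> list[EquilibriumRecord]:
        return [r for r in self.records if abs(r.T - T) <= atol and r.stable]

    def temperatures(self) -> np.ndarray:
        return np.unique([r.T for r in self.records])

    def bifurcation_temperatures(self, kind: str | None = None) -> list[float]:
        return [b.T for b in self.bifurcations if kind is None or b.kind == kind]
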