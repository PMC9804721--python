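"""Flat key-value run configuration (YAML or JSON).

The dialect is a single mapping whose keys are exactly the parameter names
``delta, m_a, m_b, m_c, T_I, beta, R_0`` (consumer), ``b_max, delta_T,
beta_r, d_0, d_1, d_2, gamma`` (logistic resource) and ``S, D`` (chemostat),
plus run plumbing: ``model`` ("chemostat" | "logistic"), ``fixture`` (a
named fixture the flat keys then override), temperature grid ``T_start /
T_stop / T_step``, mismatch grid ``dT_start / dT_stop / dT_step`` and
``out``.  Unknown keys are rejected, all of them named at once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

from .chemostat_model import ChemostatParams
from .errors import ConfigError, ParameterError
from .fixtures import get_fixture
from .thermal_rates import ConsumerParams, ResourceTraits

__all__ = ["RunConfig", "load_config", "save_config"]

_CONSUMER_KEYS = {f.name for f in fields(ConsumerParams)}
_RESOURCE_KEYS = {f.name for f in fields(ResourceTraits)}
_CHEMOSTAT_KEYS = {f.name for f in fields(ChemostatParams)}
_GRID_KEYS = {"T_start", "T_stop", "T_step", "dT_start", "dT_stop", "dT_step"}
_META_KEYS = {"model", "fixture", "out"}
_ALL_KEYS = _CONSUMER_KEYS | _RESOURCE_KEYS | _CHEMOSTAT_KEYS | _GRID_KEYS | _META_KEYS


@dataclass(frozen=True)
class RunConfig:
    """A validated run: model choice, parameter objects and grids."""

    model: str | None
    consumer: ConsumerParams
    resource: ResourceTraits | None = None
    chemostat: ChemostatParams | None = None
    fixture: str | None = None
    T_start: float = 0.0
    T_stop: float = 40.0
    T_step: float = 0.05
    dT_start: float = -25.0
    dT_stop: float = 15.0
    dT_step: float = 1.0
    out: str | None = None

    def T_grid(self) -> np.ndarray:
        return np.arange(self.T_start, self.T_stop + self.T_step / 2, self.T_step)

    def dT_grid(self) -> np.ndarray:
        return np.arange(self.dT_start, self.dT_stop + self.dT_step / 2, self.dT_step)

    def params_for_model(self):
        if self.model == "chemostat":
            if self.chemostat is None:
                raise ConfigError("model 'chemostat' needs S and D")
            return self.chemostat
        if self.model == "logistic":
            if self.resource is None:
                raise ConfigError("model 'logistic' needs resource traits")
            return self.resource
        raise ConfigError(f"no model selected (got {self.model!r})")


def _build(raw: dict) -> RunConfig:
    unknown = sorted(set(raw) - _ALL_KEYS)
    if unknown:
        raise ConfigError("unknown config keys: " + ", ".join(unknown))

    fixture = raw.get("fixture")
    consumer = ConsumerParams()
    resource = None
    chemostat = None
    model = raw.get("model")
    if fixture is not None:
        fx = get_fixture(fixture)
        consumer = fx.get("consumer", consumer)
        resource = fx.get("resource")
        chemostat = fx.get("chemostat")
        model = model or fx.get("model")

    problems: list[str] = []

    def override(obj, keys, factory):
        given = {k: float(raw[k]) for k in keys if k in raw}
        if not given and obj is not None:
            return obj
        try:
            return replace(obj, **given) if obj is not None else factory(**given)
        except ParameterError as e:
            problems.append(str(e))
            return obj

    consumer = override(consumer, _CONSUMER_KEYS, ConsumerParams)
    if any(k in raw for k in _RESOURCE_KEYS) or resource is not None:
        resource = override(resource, _RESOURCE_KEYS, ResourceTraits)
    if any(k in raw for k in _CHEMOSTAT_KEYS) or chemostat is not None:
        chemostat = override(chemostat, _CHEMOSTAT_KEYS, ChemostatParams)
    if problems:
        raise ConfigError("; ".join(problems))

    grid = {k: float(raw[k]) for k in _GRID_KEYS if k in raw}
    return RunConfig(model=model, consumer=consumer, resource=resource,
                     chemostat=chemostat, fixture=fixture, out=raw.get("out"),
                     **grid)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return _build(raw)


def save_config(cfg: RunConfig, path) -> None:
    """Serialize back to the flat dialect (YAML by default, JSON by suffix)."""
    flat: dict = {}
    for obj in (cfg.consumer, cfg.resource, cfg.chemostat):
        if obj is not None:
            flat.update({f.name: getattr(obj, f.name) for f in fields(obj)})
    for k in ("model", "fixture", "out"):
        v = getattr(cfg, k)
        if v is not None:
            flat[k] = v
    for k in _GRID_KEYS:
        flat[k] = getattr(cfg, k)
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(flat, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(flat, sort_keys=True))
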