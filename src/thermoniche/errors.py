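"""Typed errors shared across the package."""


class ThermonicheError(Exception):
    """Base class for all package errors."""


class ParameterError(ThermonicheError, ValueError):
    """A parameter set violates its invariants; message names every offending field."""


class ConfigError(ThermonicheError, ValueError):
    """A configuration file failed validation; message lists every offending key."""


class NoNicheError(ThermonicheError):
    """No temperature permits positive consumer growth at the requested resource level."""


class NoCoexistenceError(ThermonicheError):
    """The consumer cannot persist on the resource anywhere on the temperature axis."""


class IntegrationError(ThermonicheError):
    """The ODE solver failed; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
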