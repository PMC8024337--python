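"""Exception hierarchy for the simulator."""


class CytosimError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CytosimError, ValueError):
    """A configuration or argument value violates its contract."""


class IntegrityError(CytosimError, RuntimeError):
    """Internal state violated an invariant (conservation, dangling ids, ...)."""


class CalibrationError(CytosimError, RuntimeError):
    """Grid search could not reach the requested target."""
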