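"""Exception hierarchy shared across the package."""


class SwitchsimError(Exception):
    """Base class for all package-specific errors."""


class ModelValidationError(SwitchsimError, ValueError):
    """A state graph or one of its components violates a structural invariant."""


class ConfigurationError(SwitchsimError, ValueError):
    """A configuration value is missing, unknown, or out of range."""


class SimulationError(SwitchsimError, RuntimeError):
    """The master-equation integrator failed; carries state/rate diagnostics."""


class FitError(SwitchsimError, RuntimeError):
    """A least-squares fit failed to converge or its input is unusable."""


class ClassificationError(SwitchsimError, KeyError):
    """A trajectory state could not be mapped to an on/off/neither class."""
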