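"""Exception types shared across the package."""


class FractcmError(Exception):
    """Base class for package-specific errors."""


class IntegrationFailureError(FractcmError):
    """The fractional/ODE integrator produced a non-finite state.

    Carries ``time``, the grid time at which integration failed.
    """

    def __init__(self, message: str, time: float):
        super().__init__(message)
        self.time = time


class ConfigurationError(FractcmError):
    """Invalid configuration (bad distribution spec, non-normalizing density, ...)."""


class FitFailureError(FractcmError):
    """Model simulation failed during objective evaluation.

    Carries ``parameters``, the offending parameter vector.
    """

    def __init__(self, message: str, parameters=None):
        super().__init__(message)
        self.parameters = parameters


class GenerationFailureError(FractcmError):
    """Synthetic-data generation failed (underlying simulation error)."""
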