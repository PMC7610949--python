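"""Exception types shared across the package."""


class MoodsimError(Exception):
    """Base class for all package-specific errors."""


class InvalidObservationError(MoodsimError, ValueError):
    """An outcome index is outside the model's outcome space."""


class InvalidPolicyError(MoodsimError, ValueError):
    """A policy is not a member of the model's policy set."""


class BeliefNormalizationError(MoodsimError, ValueError):
    """A belief distribution handed to an operation does not sum to one."""


class NumericalError(MoodsimError, FloatingPointError):
    """NaN or infinity encountered where a finite quantity is required."""


class ConfigError(MoodsimError, ValueError):
    """A configuration value is malformed or out of range."""


class StateError(MoodsimError, RuntimeError):
    """An operation was invoked in an invalid simulation state."""
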