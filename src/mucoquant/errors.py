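"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`MucoquantError`
so callers can catch pipeline failures without masking programming errors.
"""


class MucoquantError(Exception):
    """Base class for all mucoquant errors."""


class ParameterError(MucoquantError, ValueError):
    """An argument violates a documented precondition."""


class InputError(MucoquantError, ValueError):
    """Input data are malformed (non-finite pixels, shape mismatch, ...)."""


class PlacementError(MucoquantError, RuntimeError):
    """Rejection sampling could not place an object under its constraints."""


class MeasurementError(MucoquantError, RuntimeError):
    """A statistic is undefined for the given geometry (degenerate fit, zero signal)."""


class UndefinedAngleError(MeasurementError):
    """Centroids coincide, so the tip angle is undefined for this pair."""


class EmptyResultError(MucoquantError, RuntimeError):
    """A stage produced no usable records (no sites after filtering, no peak)."""


class ConfigurationError(MucoquantError, ValueError):
    """Simulation parameters are mutually inconsistent."""
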