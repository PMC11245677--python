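"""Exception hierarchy shared across the package."""


class SegclockError(Exception):
    """Base class for all package-specific errors."""


class DomainError(SegclockError, ValueError):
    """An argument is outside the mathematically valid domain."""


class ConfigurationError(SegclockError, ValueError):
    """A configuration block is missing a field or holds an invalid value."""


class CalibrationError(SegclockError, RuntimeError):
    """Diffusion calibration failed to reach the requested tolerance."""


class IntegrationError(SegclockError, RuntimeError):
    """The DDE integration produced a non-finite state."""
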