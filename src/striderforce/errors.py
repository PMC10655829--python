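"""Exception hierarchy for the striderforce pipeline."""


class StriderforceError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(StriderforceError):
    """A parameter violates a documented precondition."""


class TrackingError(StriderforceError):
    """Marker tracking failed (lost marker, gap too long, out of view)."""


class OnsetError(StriderforceError):
    """No stroke onset could be located in the series."""


class CrossingError(StriderforceError):
    """The leg-angle series never reaches the 90 degree reference angle."""
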