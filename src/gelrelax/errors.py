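"""Exception hierarchy for the gelrelax pipeline.

Every error raised by the package derives from :class:`GelRelaxError`, so
callers can catch pipeline failures without masking programming errors.
"""


class GelRelaxError(Exception):
    """Base class for all gelrelax errors."""


class FormatError(GelRelaxError):
    """A trace or result file does not match the documented layout."""


class ConfigError(GelRelaxError):
    """An experiment configuration value is missing or inconsistent."""


class TraceValidationError(GelRelaxError):
    """A trace violates a structural invariant (e.g. non-monotone time)."""


class ContactNotFoundError(GelRelaxError):
    """No sustained touch-load crossing was found in the approach."""


class GeometryError(GelRelaxError):
    """Detected geometry is impossible (e.g. negative gel thickness)."""


class TruncatedTraceError(GelRelaxError):
    """The trace ends before the constant-strain hold completes.

    Carries the partial phase-labelled trace on ``.partial`` so callers can
    still inspect the data that was recorded.
    """

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


class DegenerateRampError(GelRelaxError):
    """Ramp samples have no strain variation; no stiffness slope exists."""


class UndefinedRelaxationError(GelRelaxError):
    """Total relaxation is undefined (non-positive initial stiffness)."""


class UndefinedRIError(GelRelaxError):
    """Relative importance is undefined because all element stiffnesses are 0."""


class EmptyGroupError(GelRelaxError):
    """A summary was requested for a group with no members."""
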