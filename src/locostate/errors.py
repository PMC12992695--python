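"""Exception hierarchy shared across the toolchain."""


class LocostateError(Exception):
    """Base class for all package errors."""


class FormatError(LocostateError):
    """A file could not be parsed in the requested dialect."""


class StructureError(LocostateError):
    """A file parsed but its internal structure is inconsistent."""


class ValidationError(LocostateError):
    """Data violates a documented invariant (e.g. overlapping events)."""


class ConfigurationError(LocostateError):
    """An invalid parameter or configuration value was supplied."""


class InsufficientDataError(LocostateError):
    """Not enough samples/subjects/frames to perform the computation."""


class DegenerateSignalError(LocostateError):
    """Signal has zero variance where a spectral ratio is required."""


class DegenerateGeometryError(LocostateError):
    """A zero-length limb vector makes a joint angle undefined."""


class AmbiguousDirectionError(LocostateError):
    """Net displacement too small to infer the direction of travel."""


class ShapeError(LocostateError):
    """Array dimensions do not match the model's expectation."""
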