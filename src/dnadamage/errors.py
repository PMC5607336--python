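"""Exception hierarchy of the simulation chain."""


class DnaDamageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DnaDamageError):
    """Invalid configuration value, unknown key or inconsistent table."""


class ConstructionError(DnaDamageError):
    """A geometry element could not be assembled from its specification."""


class PackingError(DnaDamageError):
    """Domain placement failed; carries the achieved packing fraction."""

    def __init__(self, message: str, achieved_fraction: float = 0.0):
        super().__init__(message)
        self.achieved_fraction = achieved_fraction


class GeometryStateError(DnaDamageError):
    """Operation requires a state (e.g. a spatial index) that is missing."""


class GeometryParseError(DnaDamageError):
    """Geometry file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number
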