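"""Exception hierarchy shared across the package."""


class KneeplanError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(KneeplanError, ValueError):
    """A parameter or specification value violates its invariant.

    The message always names the offending field.
    """


class GeometryError(KneeplanError, RuntimeError):
    """A mesh operation produced (or received) invalid geometry."""


class ExtentError(GeometryError):
    """A mesh is too short / small for the requested construction."""


class MeasurementError(KneeplanError, RuntimeError):
    """A geometric measurement could not be completed (e.g. ray miss)."""


class PlacementError(KneeplanError, RuntimeError):
    """Component placement failed (degenerate axes, unreachable target)."""


class FormatError(KneeplanError, ValueError):
    """A file could not be parsed.

    ``byte_offset`` locates the problem when it is known.
    """

    def __init__(self, message: str, byte_offset: int | None = None):
        super().__init__(message)
        self.byte_offset = byte_offset
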