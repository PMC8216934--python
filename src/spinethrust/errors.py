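"""Exception hierarchy for the spinethrust pipeline."""


class SpineThrustError(Exception):
    """Base class for all package errors."""


class MalformedContourError(SpineThrustError):
    """A contour violates a structural precondition (too few points, duplicates)."""


class ContourParseError(SpineThrustError):
    """A contour file contains rows that cannot be parsed as coordinates."""


class SchemaError(SpineThrustError):
    """A tabular input is missing a required column."""


class UniquenessError(SpineThrustError):
    """Duplicate specimen identifiers within one manifest."""


class ParameterError(SpineThrustError):
    """A smoothing parameter is invalid for the contour being processed."""


class DegenerateGeometryError(SpineThrustError):
    """Coincident points where a triangle or a frame axis was required."""


class UndefinedCorrelationError(SpineThrustError):
    """Pearson correlation requested on a zero-variance sequence."""


class PairingError(SpineThrustError):
    """Repeatability inputs that cannot be paired by specimen id."""


class TuningError(SpineThrustError):
    """Grid search ended with no defined cell."""


class GeneratorError(SpineThrustError):
    """Synthetic shape parameters that do not produce five distinct extrema."""
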