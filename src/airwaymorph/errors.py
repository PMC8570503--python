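"""Exception hierarchy for the airway morphometry pipeline."""


class AirwayMorphError(Exception):
    """Base class for all package errors."""


class ValidationError(AirwayMorphError):
    """An input object violates one of its documented invariants."""


class DegenerateGeometryError(AirwayMorphError):
    """Geometric construction is ill-posed (collinear / coincident points)."""


class BoundaryError(AirwayMorphError):
    """Boundary planes are inconsistent or fall outside the volume."""


class EmptyInputError(AirwayMorphError):
    """An operation that requires foreground received an empty mask/profile."""


class SeedPointError(AirwayMorphError):
    """Dead-space removal seed does not lie on foreground."""


class OrderingError(AirwayMorphError):
    """Landmark superior-to-inferior ordering is violated."""


class DataError(AirwayMorphError):
    """Input data is structurally invalid (non-finite HU, missing timepoint...)."""


class FormatError(AirwayMorphError):
    """File cannot be read or is missing required metadata."""


class UndefinedStatisticError(AirwayMorphError):
    """A statistic is undefined for this input (zero variance, zero mean)."""


class UndefinedParameterError(AirwayMorphError):
    """A derived parameter has a zero denominator; message names the parameter."""


class SampleSizeError(AirwayMorphError):
    """Too few observations for the requested statistic."""
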