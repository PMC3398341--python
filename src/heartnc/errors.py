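"""Exception hierarchy.

``HeartNCError`` is the common base; ``ValidationError`` subclasses signal
bad user input (CLI exit code 2), everything else is a stage failure
(exit code 1).
"""


class HeartNCError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HeartNCError):
    """Invalid input or configuration supplied by the caller."""


class GridMismatchError(ValidationError):
    """Voxel grids differ in shape, spacing or origin where identity is required."""


class EmptyInputError(ValidationError):
    """An operation received an empty mask, mesh or collection."""


class ComponentError(ValidationError):
    """A mask holds more than one connected component where one is required."""


class TopologyError(ValidationError):
    """A surface mesh is not closed / consistently oriented."""


class IndexAlignmentError(ValidationError):
    """A deformation field's length does not match its mesh's vertex count."""


class ParameterError(ValidationError):
    """A parameter record violates its invariants."""


class GeometryError(ValidationError):
    """Geometric precondition violated (e.g. heart outside thorax, degenerate bbox)."""


class CalibrationError(ValidationError):
    """Degenerate graticule calibration (coincident points)."""


class AnnotationError(ValidationError):
    """Required image annotations (landmarks, contour) are missing."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class MeasurementError(HeartNCError):
    """A thorax measurement could not be taken on a profile row."""


class NoCandidateError(ValidationError):
    """No same-group reference candidate exists for a test subject."""


class BoundsError(ValidationError):
    """A navigator-channel rectangle falls outside the image."""


class NoEdgeError(HeartNCError):
    """An intensity profile holds no detectable edge."""

    def __init__(self, message, role=None):
        super().__init__(message)
        self.role = role


class ConfigurationError(ValidationError):
    """Inconsistent channel / region configuration."""


class DegenerateTestError(HeartNCError):
    """Paired t-test on differences with zero variance."""
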