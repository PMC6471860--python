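"""Exception hierarchy for the awvct pipeline.

Every stage raises a subclass of :class:`AwvctError` so callers can
distinguish pipeline failures from programming errors.  The CLI maps these
to exit codes per failure class.
"""


class AwvctError(Exception):
    """Base class for all awvct errors."""

    exit_code = 1


class InvalidParameterError(AwvctError, ValueError):
    """A parameter violates its documented precondition."""

    exit_code = 2


class GeometryError(AwvctError):
    """A geometric object does not fit, or grids disagree."""

    exit_code = 3


class HeaderError(AwvctError):
    """A CT header is missing required geometry information."""

    exit_code = 4


class AmbiguousSeriesError(HeaderError):
    """A DICOM directory holds more than one series."""


class AlignmentError(GeometryError):
    """Mask geometry does not match its reference CT volume."""


class ValidationError(AwvctError):
    """Metrics fail a consistency or completeness check."""

    exit_code = 5


class SeedNotFoundError(AwvctError):
    """No plausible tracheal air component near the cranial end."""

    exit_code = 6


class InvalidSeedError(AwvctError):
    """The supplied seed voxel cannot start region growing."""

    exit_code = 6


class SegmentationFailedError(AwvctError):
    """Segmentation produced an empty or implausible result."""

    exit_code = 7


class EmptyInputError(AwvctError, ValueError):
    """An operation received an empty mask/table where content is required."""

    exit_code = 8


class MultipleComponentsError(AwvctError):
    """A centerline or mask is disconnected where connectivity is required."""

    exit_code = 9


class GraphTopologyError(AwvctError):
    """The skeleton graph is not a tree (cycles or inconsistent structure)."""

    exit_code = 9


class MissingLabelsError(AwvctError):
    """A graph operation requires subtree labels that are absent."""

    exit_code = 10


class InvalidPartitionError(AwvctError):
    """Requested subtree roots cannot partition the tree (ancestor pair)."""

    exit_code = 10


class InvalidCenterError(AwvctError):
    """A cross-section center does not sit in a low-attenuation lumen."""

    exit_code = 11


class QualityError(AwvctError):
    """Too many rays failed for a cross-section measure to be trusted."""

    exit_code = 11


class UndefinedMeasureError(AwvctError):
    """A density measure was requested over an empty region."""

    exit_code = 12


class DomainError(AwvctError, ValueError):
    """An index received an argument outside its physiological domain."""

    exit_code = 13


class ConfigError(AwvctError):
    """Configuration is malformed, references missing files, or unknown keys."""

    exit_code = 14


class SimulationError(AwvctError):
    """Cohort simulation spec is unusable (e.g. singular correlation)."""

    exit_code = 15


class InsufficientDataError(AwvctError):
    """Too few observations for the requested statistic."""

    exit_code = 16


class SingularDesignError(AwvctError):
    """Perfect collinearity in a regression design matrix."""

    exit_code = 16


class PipelineStageError(AwvctError):
    """Wraps a stage failure with the stage name for provenance."""

    exit_code = 20

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
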