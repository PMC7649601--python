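"""Exception hierarchy for the brace-root biomechanics pipeline."""


class BraceMechError(Exception):
    """Base class for all package-specific errors."""


class TraceFormatError(BraceMechError):
    """Trace or metadata file violates the expected CSV dialect."""


class TraceParseError(BraceMechError):
    """A cell in a trace file could not be parsed as a number."""


class InsufficientDataError(BraceMechError):
    """Fewer samples/groups/traces than the operation requires."""


class ContiguityError(BraceMechError):
    """Removal-series test labels do not form a contiguous run from 'A'."""


class LabelConflictError(BraceMechError):
    """Two traces carry the same test label for one plant."""


class NoCycleError(BraceMechError):
    """No loading cycle passed the run-length and span filters."""


class DegenerateFitError(BraceMechError):
    """A line fit is undefined (zero deflection variance, all outliers, ...)."""


class GeometryError(BraceMechError):
    """Beam geometry is invalid (attachment height >= load height, h <= 0)."""


class DomainError(BraceMechError):
    """Input outside the mathematical domain of the operation."""


class ParameterError(BraceMechError):
    """Configuration parameter outside its allowed range."""


class SingularDesignError(BraceMechError):
    """Regression design matrix is rank deficient."""
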