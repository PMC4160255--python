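"""Exception hierarchy for ewdclim.

Every error raised by the library derives from :class:`EwdClimError` so that
callers (and the CLI) can distinguish validation problems from genuine bugs.
"""


class EwdClimError(Exception):
    """Base class for all ewdclim errors."""


class ParseError(EwdClimError):
    """A measurement or climate file is malformed; message names the line."""


class ConflictError(EwdClimError):
    """Duplicate (series, year) encountered while parsing."""


class SchemaError(EwdClimError):
    """Tabular input does not match the expected column layout or bounds."""


class GapError(EwdClimError):
    """Year axis of a climate table is not contiguous."""


class IdentifierError(EwdClimError):
    """Series identifier cannot be represented in the output format."""


class InsufficientDataError(EwdClimError):
    """Too few values/years for the requested operation."""


class DegenerateSeriesError(EwdClimError):
    """A measurement series carries no usable information (e.g. all zero)."""


class CoverageGapError(EwdClimError):
    """A year inside the union span of the series is covered by no series."""


class EmptyReliablePeriodError(EwdClimError):
    """No year satisfies the chronology reliability rule."""


class AlignmentError(EwdClimError):
    """Climate record does not cover the months required by the window."""


class RankError(EwdClimError):
    """Fewer observations than retained principal components."""


class DegenerateControlError(EwdClimError):
    """Control variable is perfectly collinear with x or y."""


class SingularFitError(EwdClimError):
    """Predictor is constant; regression is singular."""


class UndefinedDenominatorError(EwdClimError):
    """Observed values all equal the calibration mean; RE undefined."""


class DegenerateSplitError(EwdClimError):
    """Product-means test: one of the sign groups is empty (all-agreement)."""


class DegenerateVarianceError(EwdClimError):
    """Product-means test: zero variance in both groups, t undefined."""


class NyquistError(EwdClimError):
    """Low-pass cutoff at or below two years is not resolvable annually."""


class OverlapError(EwdClimError):
    """No grid cell shares enough years with the series."""


class SelectionError(EwdClimError):
    """Composite selection size exceeds half the available years."""


class StationarityError(EwdClimError):
    """AR(1) coefficient outside (-1, 1)."""


class ConfigError(EwdClimError):
    """Generator or run configuration is inconsistent."""


class StageError(EwdClimError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
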