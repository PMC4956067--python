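"""Exception hierarchy.

Everything raised deliberately by skillmatch derives from :class:`SkillMatchError`,
and everything that signals bad *input* (rather than an unexpected failure)
derives from :class:`ValidationError`, which the CLI maps to exit code 2.
"""


class SkillMatchError(Exception):
    """Base class for all skillmatch errors."""


class ValidationError(SkillMatchError, ValueError):
    """Invalid input data, configuration, or arguments."""


class FormatError(ValidationError):
    """A file is not in the expected format (bad magic, unknown version)."""


class CorruptFileError(ValidationError):
    """A stream file is structurally damaged (e.g. truncated mid-frame)."""

    def __init__(self, message: str, frame_index: int | None = None):
        super().__init__(message)
        self.frame_index = frame_index


class RuleSyntaxError(ValidationError):
    """A rule file failed to parse."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        loc = f" (line {line}, column {column})" if line is not None else ""
        super().__init__(message + loc)
        self.line = line
        self.column = column


class MissingLandmarkError(ValidationError):
    """A landmark joint required for calibration is not tracked."""


class CalibrationRejectedError(ValidationError):
    """The two cameras' wrist spans disagree by 10 cm or more."""


class NoOverlapError(ValidationError):
    """Two streams to be fused do not overlap in time."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(ValidationError):
    """The data carry no variance, so the statistic is undefined."""
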