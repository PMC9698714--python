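"""Exception hierarchy for the oegait pipeline.

Every stage raises a subclass of :class:`GaitAnalysisError`; the CLI maps
bad-input errors to exit code 2 and insufficient-gait errors to exit code 3.
"""


class GaitAnalysisError(Exception):
    """Base class for all oegait errors."""


class FormatError(GaitAnalysisError):
    """Input file does not match the declared column mapping / dialect."""


class DataError(GaitAnalysisError):
    """Input data violates a structural invariant (e.g. non-monotonic time)."""


class InsufficientDataError(GaitAnalysisError):
    """Recording or window too short for the requested operation."""


class CalibrationError(GaitAnalysisError):
    """Neutral-pose window is not quasi-static or otherwise unusable."""


class DegenerateInputError(GaitAnalysisError):
    """Mathematically degenerate input (zero-norm gravity vector, flat spectrum...)."""


class ParameterError(GaitAnalysisError):
    """Invalid parameter value or unknown mode/preset name."""


class MissingMetadataError(GaitAnalysisError):
    """Operation needs recording metadata (distance, speed, mass) that is absent."""


class InsufficientGaitError(GaitAnalysisError):
    """Too few detected steps to form a steady-state segment."""


class UndefinedRatioError(GaitAnalysisError):
    """A ratio metric (OEP, EP%) is undefined for this input (zero denominator)."""


BAD_INPUT_ERRORS = (
    FormatError,
    DataError,
    ParameterError,
    MissingMetadataError,
    DegenerateInputError,
    CalibrationError,
    InsufficientDataError,
)
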