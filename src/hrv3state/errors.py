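"""Exception hierarchy for the HRV screening pipeline."""


class HRVError(Exception):
    """Base class for all pipeline errors."""


class ParseError(HRVError):
    """Malformed input file; message names the offending line."""


class FormatError(HRVError):
    """Structurally readable input violating a format precondition."""


class DetectionError(HRVError):
    """R-peak detection cannot proceed (e.g. flat-line ECG)."""


class InsufficientDataError(HRVError):
    """Too little signal for the requested operation."""


class RRCleaningError(HRVError):
    """Artifact pattern outside the correctable class (consecutive out-of-range beats)."""


class CoverageError(HRVError):
    """Trend does not span the requested state plan."""


class DivisionGuardError(HRVError):
    """A Rest-state average is zero so a response ratio is undefined."""


class ValidationError(HRVError):
    """Value outside its documented domain."""


class ModelError(HRVError):
    """Discriminant or AR model fitting failure (singular/degenerate)."""


class ParameterError(HRVError):
    """Simulator parameters imply an impossible physiological signal."""
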