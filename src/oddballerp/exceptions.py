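"""Exception hierarchy for the oddball-ERP pipeline."""


class OddballError(Exception):
    """Base class for all package errors."""


class ConstraintError(OddballError, ValueError):
    """An impossible combination of generation constraints was requested."""


class ConfigurationError(OddballError, KeyError):
    """A calibration or pipeline configuration entry is missing or malformed."""


class StructuralError(OddballError, ValueError):
    """Array shapes or axes do not line up (channel lengths, epoch axes)."""


class ParameterError(OddballError, ValueError):
    """An operation parameter is outside its allowed set (e.g. even filter taps)."""


class InsufficientDataError(OddballError, ValueError):
    """Too few trials/epochs to compute the requested quantity."""


class InvariantError(OddballError, ValueError):
    """A measurement invariant (e.g. T1 < FAL < T2) is violated."""


class RankError(OddballError, ValueError):
    """Design matrix is rank deficient (constant predictor, collinear covariates)."""


class FitError(OddballError, RuntimeError):
    """Model fitting failed (non-convergence, perfect separation)."""


class ReportError(OddballError, ValueError):
    """Report tables cannot be built (e.g. an empty group)."""


class FormatError(OddballError, ValueError):
    """An on-disk session/feature file is malformed."""
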