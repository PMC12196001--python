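"""Exception hierarchy for the dyadsync pipeline."""


class DyadsyncError(Exception):
    """Base class for all dyadsync errors."""


class ValidationError(DyadsyncError):
    """Input data or parameters violate a documented precondition."""


class ParameterError(ValidationError):
    """A configuration parameter is out of its valid range."""


class FormatError(DyadsyncError):
    """A file could not be parsed; the message names the first offending record."""


class DyadCompletenessError(FormatError):
    """A recording file does not contain exactly two subjects."""


class MarkerMissingError(FormatError):
    """A recording lacks the video-onset time markers."""


class GeometryError(DyadsyncError):
    """Channel geometry is unusable (e.g. singular extinction matrix)."""


class IrrecoverableChannelError(DyadsyncError):
    """Despiking flagged every sample of a channel; nothing clean remains."""


class InfeasibleWindowError(DyadsyncError):
    """The DTW window constraint admits no warping path."""


class CollinearityError(DyadsyncError):
    """The regression design matrix is rank deficient."""


class UndefinedCorrelationError(DyadsyncError):
    """Pearson correlation requested on a constant input."""


class EmptyCohortError(DyadsyncError):
    """Every dyad was lost to quality filtering; no rows enter the statistics."""


class TruncationError(DyadsyncError):
    """The event schedule overruns the recorded series."""
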