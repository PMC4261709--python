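"""Exception hierarchy for dyadscope.

Every error raised by the public API derives from :class:`DyadscopeError`,
so callers can catch one base class at pipeline level.
"""


class DyadscopeError(Exception):
    """Base class for all dyadscope errors."""


class BundleIncomplete(DyadscopeError):
    """A mandatory file of the recording bundle is missing."""


class ParseError(DyadscopeError):
    """A bundle file is malformed; message names file and location."""


class IOFailure(DyadscopeError):
    """A bundle could not be written."""


class EmptyClock(DyadscopeError):
    """resample_to_clock received an empty target clock."""


class DegenerateConfiguration(DyadscopeError):
    """Too few or collinear correspondence points for rigid estimation."""


class InvalidPoint(DyadscopeError):
    """Non-finite coordinates in calibration input."""


class NoClapFound(DyadscopeError):
    """No audio window crossed the clap detection threshold."""


class AmbiguousIdentity(DyadscopeError):
    """Two tracked slots claimed the same seat for too long."""


class InvalidWindow(DyadscopeError):
    """Smoothing window must be an odd positive frame count."""


class EmptySegment(DyadscopeError):
    """Phase segmentation produced no usable segment."""


class TooShort(DyadscopeError):
    """Audio shorter than a single analysis frame."""


class OutOfRange(DyadscopeError):
    """A behavior-coding item code lies outside the 1-5 scale."""


class SchemaMismatch(DyadscopeError):
    """A behavior-coding record does not contain the canonical item set."""


class ProfileError(DyadscopeError):
    """Invalid synthetic dyad profile parameters."""


class StageError(DyadscopeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


class EmptyReport(DyadscopeError):
    """render_report received an empty results directory."""
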