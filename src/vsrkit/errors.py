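"""Exception types raised by vsrkit.

Parameter-validation problems raise plain :class:`ValueError`; everything that
reflects a property of the *data* (an untrackable frame, a trace with too few
marker frames, a cycle with no usable frames, ...) gets a dedicated class so
callers can distinguish "bad input" from "bad recording".
"""


class VsrError(Exception):
    """Base class for vsrkit data errors."""


class RenderError(VsrError):
    """Requested larva geometry does not fit inside the image."""


class TrackingFailure(VsrError):
    """A single frame could not be tracked (no body region, border contact, ...)."""


class UnusableRecordingError(VsrError):
    """Too many frames failed tracking for the recording to be analyzed."""


class SegmentationError(VsrError):
    """The trace cannot be segmented into cycles (fewer than 2 black frames)."""


class DegenerateCycleError(VsrError):
    """A cycle contains no valid frames, so its metrics are undefined."""


class UndefinedHalfTimeError(VsrError):
    """Half-time is undefined because the initial baseline response is zero."""


class DegenerateTrialError(VsrError):
    """A trial has no retained cycles."""


class ProtocolError(VsrError):
    """Epoch/rest schedule information required by an operation is missing."""


class InsufficientDataError(VsrError):
    """Too few observations for the requested statistic."""


class MissingCellError(VsrError):
    """A genotype x cycle cell of the group table is empty."""
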