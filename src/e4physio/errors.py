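"""Exception hierarchy for session parsing and analysis."""


class E4Error(Exception):
    """Base class for all package errors."""


class UnreadableArchive(E4Error):
    """The zip archive is missing, empty, or not a readable zip."""


class BadDialect(E4Error):
    """A CSV does not follow the expected session-archive layout."""


class NonMonotoneBeats(BadDialect):
    """Beat offsets in an inter-beat-interval table decrease."""


class BadInterval(BadDialect):
    """An inter-beat interval is zero or negative."""


class NotSameDay(E4Error):
    """Archives passed for merging were recorded on different calendar days."""


class OverlapError(E4Error):
    """Recordings passed for merging overlap in time."""


class DownsamplingUnsupported(E4Error):
    """The preprocessing stage only upsamples; input fs exceeds the target."""


class ModelMismatch(E4Error):
    """Classifier model refers to features the feature vector lacks."""


class InsufficientBeats(E4Error):
    """Fewer than two accepted beats; HRV measures undefined."""


class InsufficientDuration(E4Error):
    """Series shorter than the minimum needed for spectral analysis."""


class NoAnalyzableData(E4Error):
    """No valid samples (or zero analyzable duration) in the interval."""


class OutOfRange(E4Error):
    """Requested time span lies outside the session."""


class BadCalendarSchema(E4Error):
    """Calendar table lacks one of the required columns."""


class EventsTooClose(E4Error):
    """Synthetic SCR events overlap (separation < rise + 3x decay)."""


class NothingToProcess(E4Error):
    """Batch input folder contains no archives."""
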