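"""Exception hierarchy for annotation-package validation and measures."""


class EvalkitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(EvalkitError):
    """A file exists but is not in the expected format (dtype, columns)."""


class GapError(EvalkitError):
    """A frame is missing inside a contiguous numbered sequence."""


class GeometryError(EvalkitError):
    """Frames or frame pairs disagree in shape or dimensionality."""


class TrackTableError(EvalkitError):
    """A track table violates its structural invariants."""


class AnnotationError(EvalkitError):
    """Pixel data and track table disagree (orphan labels, span gaps)."""


class UndefinedMeasureError(EvalkitError):
    """The requested measure has no defined value on this input
    (e.g. SEG with zero annotated reference instances)."""


class InfeasibleInjectionError(EvalkitError):
    """The corruption request cannot be honoured on this scene
    (not enough distinct cells/frames for non-interacting placement)."""
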