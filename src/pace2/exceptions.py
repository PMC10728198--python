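"""Exception types shared across the pipeline stages."""


class Pace2Error(Exception):
    """Base class for all pipeline errors."""


class UnsupportedFormatError(Pace2Error):
    """Raised for color images, multi-frame DICOMs, or unreadable rasters."""


class InsufficientExtremaError(Pace2Error):
    """Fewer than two extrema of a type: envelope width is undefined.

    The decomposition loop catches this and stops early.
    """


class InvalidMaskError(Pace2Error):
    """A contrast mask with an empty foreground or background."""


class DegenerateReferenceError(Pace2Error):
    """The reference image has zero region contrast, so CII is undefined."""


class InvalidConfigError(Pace2Error):
    """A configuration that violates a stage precondition (e.g. CLAHE tiles
    smaller than 2x2 pixels for the given image)."""


class InvalidSpecError(Pace2Error):
    """Phantom geometry that does not fit inside the frame."""
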