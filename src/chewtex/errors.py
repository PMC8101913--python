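"""Exception hierarchy for the chewtex pipeline.

All pipeline failures derive from :class:`ChewtexError` so batch drivers can
catch one type, log the offending specimen, and continue.
"""


class ChewtexError(Exception):
    """Base class for all chewtex errors."""


class ImageFormatError(ChewtexError):
    """File decoded but is not a usable raster image (zero-size, non-image)."""


class SegmentationError(ChewtexError):
    """No connected chromatic region large enough to be the specimen."""


class EmptySpecimenError(ChewtexError):
    """A mask with zero member pixels was passed where a specimen is required."""


class InsufficientPairsError(ChewtexError):
    """Mask too small or thin: no co-occurring pixel pair at the configured offset."""


class NoChromaticPixelsError(ChewtexError):
    """Every in-mask pixel is achromatic; variance of hue is undefined."""


class DegenerateInputError(ChewtexError):
    """Statistical input carries no information (e.g. all paired differences zero)."""
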