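"""Exception hierarchy for icgquant.

Every error raised deliberately by the library derives from
:class:`IcgquantError`, so callers (and the CLI) can catch one base class.
"""


class IcgquantError(Exception):
    """Base class for all icgquant errors."""


class ImageFormatError(IcgquantError):
    """Raised when a file does not decode as an 8-bit RGB raster."""


class BoundsError(IcgquantError, ValueError):
    """Raised when a region of interest falls outside the image."""


class EmptyROIError(IcgquantError):
    """Raised when an ROI contains no retained (green-dominant) pixels."""


class QuantificationError(IcgquantError):
    """Raised when a segment quantification has no usable pixels at all."""


class SamplingError(IcgquantError):
    """Raised when automatic ROI placement cannot satisfy its constraints."""


class EmptyGroupError(IcgquantError):
    """Raised when a study query selects no observations."""


class InsufficientDataError(IcgquantError):
    """Raised when a statistic requires more observations than supplied."""


class SpecValidationError(IcgquantError, ValueError):
    """Raised when a synthetic-data specification is infeasible or invalid."""
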