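"""Exception hierarchy.

Everything raised on bad input derives from :class:`ConjscreenError` so
callers can catch one base; each subclass also derives from ``ValueError``
to keep plain-Python idioms working.
"""


class ConjscreenError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ConjscreenError, ValueError):
    """Input violates a documented contract (shapes, labels, counts)."""


class FormatError(ConjscreenError, ValueError):
    """A file could not be parsed in the expected format."""


class UnsupportedDepthError(FormatError):
    """Image file is not an 8-bit RGB raster (e.g. grayscale or 16-bit)."""


class RangeError(ConjscreenError, ValueError):
    """A numeric value is outside its permitted range."""


class GeometryError(ConjscreenError, ValueError):
    """A polygon ROI is empty, degenerate or outside the image."""


class DegenerateCardError(ConjscreenError, ValueError):
    """The calibration card's white patch yields a zero channel mean."""


class DegenerateVarianceError(ConjscreenError, ValueError):
    """A statistic requiring non-zero variance got constant input."""


class UndefinedStatisticError(ConjscreenError, ValueError):
    """The requested statistic is undefined for this input (e.g. CV of
    zero-mean data, kappa with chance agreement equal to 1)."""


class SampleSizeError(ConjscreenError, ValueError):
    """Too few observations for the requested statistical method."""
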