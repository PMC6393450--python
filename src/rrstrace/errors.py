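"""Exception types raised by the tracing pipeline."""


class RRSError(Exception):
    """Base class for all package errors."""


class DataError(RRSError, ValueError):
    """Input pixel data is malformed (negative, NaN, empty...)."""


class FormatError(RRSError, ValueError):
    """Unsupported image file format or bit depth."""


class GeometryError(RRSError, ValueError):
    """A sampling segment or zone is geometrically invalid for the image."""


class ParameterError(RRSError, ValueError):
    """A configuration or call parameter is out of its legal range."""
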