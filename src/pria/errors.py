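"""Exception hierarchy for the pria package."""


class PriaError(Exception):
    """Base class for all pria-specific errors."""


class DegenerateWindowError(PriaError):
    """Raised when R² is requested on a window with zero total sum of squares.

    A constant window has no variance to explain, so the coefficient of
    determination is undefined rather than 0 or 1.
    """


class DegenerateDesignError(PriaError, ValueError):
    """Raised when a calibration fit has no spread in the content values."""


class FormatError(PriaError, ValueError):
    """Raised on malformed input files; the message names the offending
    row/column/well so instrument exports can be fixed in place."""
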